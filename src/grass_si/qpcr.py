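"""RT-qPCR relative expression analysis.

The pipeline mirrors standard practice for high-throughput qPCR of
tissue panels with multiple reference genes:

1. technical-replicate quality control — Ct values above a cut-off
   (default 21 cycles for pre-amplified chips) are set to a sentinel
   (999); replicate pairs differing by more than 0.5 cycles or by 3%
   or more percent deviation are excluded, every exclusion carrying a
   reason code;
2. genomic-DNA contamination check — negligible when the no-RT control
   trails the RT sample by more than 10 cycles (or never amplifies);
3. amplification-efficiency estimation from raw fluorescence curves by
   a window-of-linearity fit (best-R^2 log-linear window after baseline
   subtraction), E = 10^slope;
4. reference-gene stability (geNorm): M = mean standard deviation of
   pairwise log2 expression ratios, stepwise exclusion ranking, and
   pairwise variation V(n, n+1) of normalisation factors;
5. efficiency-corrected relative expression (Pfaffl): RQ = E^(Ct_control
   - Ct_sample), ratio = RQ_goi / geometric mean of reference RQs;
6. delta-Ct matrices — Ct of the target minus the geometric mean Ct of
   the reference genes in the same sample, for cross-gene comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QcThresholds",
    "QcResult",
    "apply_ct_qc",
    "check_gdna",
    "EfficiencyEstimate",
    "estimate_efficiency",
    "GenormResult",
    "genorm",
    "pfaffl_ratio",
    "delta_ct_matrix",
    "CT_SENTINEL",
    "REQUIRED_CT_COLUMNS",
]

CT_SENTINEL = 999.0

REQUIRED_CT_COLUMNS = ("sample_id", "bio_rep", "tissue", "timepoint",
                       "gene", "allele", "tech_rep", "ct", "rt_flag")

_GROUP_KEY = ["sample_id", "gene", "allele", "rt_flag"]


@dataclass(frozen=True)
class QcThresholds:
    """QC cut-offs with the field-standard defaults.

    `max_ct`: Ct values above this are unreliable on pre-amplified
    chips and are replaced by the sentinel. `max_rep_diff`: maximum
    absolute Ct difference between technical replicates, in cycles.
    `max_pct_dev`: exclusive upper bound on the percent deviation
    |dCt| / mean(Ct) x 100 between replicates.
    """

    max_ct: float = 21.0
    sentinel: float = CT_SENTINEL
    max_rep_diff: float = 0.5
    max_pct_dev: float = 3.0


@dataclass
class QcResult:
    """QC outcome: mean Cts of kept replicate groups plus a full audit.

    `kept` has one row per surviving (sample, gene, allele, rt_flag)
    group with its mean Ct; `report` has one row per input group with
    status and reason, so every measurement is accounted for exactly
    once.
    """

    kept: pd.DataFrame
    report: pd.DataFrame
    thresholds: QcThresholds


def _validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table is missing required columns: {missing}")
    return table


def apply_ct_qc(table: pd.DataFrame,
                thresholds: QcThresholds = QcThresholds()) -> QcResult:
    """Filter technical-replicate Ct groups against the QC thresholds.

    Per (sample, gene, allele, rt_flag) group: Ct > max_ct is first set
    to the sentinel; a group with fewer than two replicates is excluded
    ("incomplete"), with any sentinel value ("sentinel"), with a
    replicate range above `max_rep_diff` cycles ("rep_diff"), or with a
    percent deviation at or above `max_pct_dev` ("pct_dev"). With more
    than two replicates the range and deviation are taken over all of
    them.
    """
    table = _validate_ct_table(table).copy()
    t = thresholds
    table["ct_qc"] = np.where(table["ct"] > t.max_ct, t.sentinel, table["ct"])
    # treat pre-existing sentinels uniformly
    table.loc[table["ct"] >= t.sentinel, "ct_qc"] = t.sentinel

    kept_rows, report_rows = [], []
    grouped = table.groupby(_GROUP_KEY, dropna=False, sort=True)
    for key, grp in grouped:
        cts = grp["ct_qc"].to_numpy(dtype=float)
        entry = dict(zip(_GROUP_KEY, key))
        entry["n_replicates"] = len(cts)
        reason = ""
        if len(cts) < 2:
            reason = "incomplete"
        elif np.any(cts >= t.sentinel):
            reason = "sentinel"
        else:
            span = float(cts.max() - cts.min())
            pct_dev = abs(span) / float(cts.mean()) * 100.0
            if span > t.max_rep_diff:
                reason = "rep_diff"
            elif pct_dev >= t.max_pct_dev:
                reason = "pct_dev"
        if reason:
            report_rows.append({**entry, "status": "excluded", "reason": reason})
        else:
            meta = grp.iloc[0]
            kept_rows.append({**entry,
                              "bio_rep": meta["bio_rep"],
                              "tissue": meta["tissue"],
                              "timepoint": meta["timepoint"],
                              "mean_ct": float(cts.mean())})
            report_rows.append({**entry, "status": "kept", "reason": ""})
    kept = pd.DataFrame(kept_rows, columns=_GROUP_KEY + [
        "n_replicates", "bio_rep", "tissue", "timepoint", "mean_ct"])
    report = pd.DataFrame(report_rows, columns=_GROUP_KEY + [
        "n_replicates", "status", "reason"])
    return QcResult(kept=kept, report=report, thresholds=thresholds)


def check_gdna(rt_ct: float, nort_ct: Optional[float],
               threshold: float = 10.0,
               sentinel: float = CT_SENTINEL) -> bool:
    """Whether genomic-DNA carry-over is negligible for a reference gene.

    Negligible when the no-RT control never amplified (absent or
    sentinel) or trails the RT sample by more than `threshold` cycles.
    """
    if nort_ct is None or nort_ct >= sentinel or math.isnan(nort_ct):
        return True
    return (nort_ct - rt_ct) > threshold


@dataclass(frozen=True)
class EfficiencyEstimate:
    """A window-of-linearity efficiency fit."""

    efficiency: float
    window: Tuple[int, int]   # first/last cycle of the fitted window
    r_squared: float
    baseline: float
    clamped: bool = False


def estimate_efficiency(fluorescence: Sequence[float],
                        cycles: Optional[Sequence[int]] = None,
                        n_baseline: int = 5,
                        window_sizes: Tuple[int, ...] = (4, 5, 6),
                        clamp: bool = True) -> EfficiencyEstimate:
    """Estimate amplification efficiency from one raw curve.

    The baseline is the median fluorescence of the first `n_baseline`
    cycles and is subtracted. Among all windows of 4-6 consecutive
    cycles with strictly positive corrected signal, the window
    maximising the R^2 of log10(fluorescence) against cycle is fitted;
    E = 10^slope. Estimates outside (1, 2] are clamped to the boundary
    with a warning (`clamped` flag set). Raises if no window with
    positive signal exists ("no exponential phase").
    """
    f = np.asarray(fluorescence, dtype=float)
    if cycles is None:
        c = np.arange(1, len(f) + 1, dtype=float)
    else:
        c = np.asarray(cycles, dtype=float)
        if len(c) != len(f):
            raise ValueError("cycles and fluorescence must have equal length")
    if len(f) < 10:
        raise ValueError("need at least 10 cycles of readings")

    baseline = float(np.median(f[:n_baseline]))
    corrected = f - baseline
    best: Optional[Tuple[float, float, Tuple[int, int]]] = None  # (r2, slope, window)
    for size in window_sizes:
        for start in range(0, len(f) - size + 1):
            win = corrected[start:start + size]
            if np.any(win <= 0):
                continue
            x = c[start:start + size]
            y = np.log10(win)
            slope, _, r, _, _ = stats.linregress(x, y)
            r2 = r * r
            if slope <= 0:
                continue
            if best is None or r2 > best[0] + 1e-15:
                best = (r2, slope, (int(x[0]), int(x[-1])))
    if best is None:
        raise ValueError("no exponential phase: no window of consecutive "
                         "cycles with positive above-baseline signal")
    r2, slope, window = best
    e = 10.0 ** slope
    clamped = False
    if not (1.0 < e <= 2.0):
        if not clamp:
            raise ValueError(f"estimated efficiency {e:.4f} outside (1, 2]")
        warnings.warn(f"estimated efficiency {e:.4f} outside (1, 2]; clamped",
                      stacklevel=2)
        e = min(max(e, 1.0 + 1e-9), 2.0)
        clamped = True
    return EfficiencyEstimate(efficiency=float(e), window=window,
                              r_squared=float(r2), baseline=baseline,
                              clamped=clamped)


@dataclass
class GenormResult:
    """geNorm reference-gene stability analysis.

    `m_values`: initial stability measure M per gene (lower = more
    stable). `exclusion_order`: genes in the order the stepwise
    procedure removed them (least stable first); the final two remain
    unranked between themselves. `stability_ranking`: most stable
    first. `pairwise_variation`: V(n, n+1) keyed by n. `acceptable`:
    M below the conventional 1.5 cut-off.
    """

    m_values: pd.Series
    exclusion_order: List[str]
    stability_ranking: List[str]
    pairwise_variation: Dict[int, float]
    acceptable: Dict[str, bool]
    m_cutoff: float = 1.5


def _m_values(log_q: pd.DataFrame) -> pd.Series:
    """Gene-stability M for a genes x samples matrix of log2 quantities."""
    genes = log_q.index
    out = {}
    for j in genes:
        sds = [float((log_q.loc[j] - log_q.loc[k]).std(ddof=1))
               for k in genes if k != j]
        out[j] = float(np.mean(sds))
    return pd.Series(out, name="M")


def genorm(quantities: pd.DataFrame, m_cutoff: float = 1.5) -> GenormResult:
    """Reference-gene stability from a genes x samples quantity matrix.

    For each gene j, M_j is the arithmetic mean over all other genes k
    of the sample standard deviation (across samples) of
    log2(q_j / q_k). The least stable gene (highest M) is removed
    iteratively down to the final pair, giving the ranking. V(n, n+1)
    is the standard deviation across samples of log2(NF_n / NF_{n+1}),
    NF_n being the geometric mean quantity of the n most stable genes.
    All quantities must be strictly positive.
    """
    q = quantities.astype(float)
    if q.shape[0] < 2 or q.shape[1] < 2:
        raise ValueError("geNorm needs at least two genes and two samples")
    if (q <= 0).any().any():
        raise ValueError("geNorm requires strictly positive quantities")
    log_q = np.log2(q)

    initial_m = _m_values(log_q)
    remaining = list(q.index)
    exclusion: List[str] = []
    while len(remaining) > 2:
        m = _m_values(log_q.loc[remaining])
        worst = m.idxmax()
        exclusion.append(worst)
        remaining.remove(worst)
    ranking = remaining + exclusion[::-1]  # most stable first

    pairwise_variation: Dict[int, float] = {}
    n_genes = q.shape[0]
    for n in range(2, n_genes):
        top_n = ranking[:n]
        top_n1 = ranking[:n + 1]
        nf_n = log_q.loc[top_n].mean(axis=0)       # log2 of geometric mean
        nf_n1 = log_q.loc[top_n1].mean(axis=0)
        pairwise_variation[n] = float((nf_n - nf_n1).std(ddof=1))

    return GenormResult(
        m_values=initial_m,
        exclusion_order=exclusion,
        stability_ranking=ranking,
        pairwise_variation=pairwise_variation,
        acceptable={g: bool(initial_m[g] < m_cutoff) for g in q.index},
        m_cutoff=m_cutoff,
    )


def _mean_ct_lookup(kept: pd.DataFrame) -> Dict[Tuple[str, str], float]:
    """(sample_id, target) -> mean Ct from a QC `kept` table (RT rows).

    The target key is the gene name, suffixed with '.<allele>' when an
    allele is recorded (allele-specific assays)."""
    rt = kept[kept["rt_flag"] == "RT"] if "rt_flag" in kept.columns else kept
    lookup: Dict[Tuple[str, str], float] = {}
    for _, row in rt.iterrows():
        allele = str(row.get("allele", "") or "")
        target = row["gene"] if not allele else f"{row['gene']}.{allele}"
        lookup[(row["sample_id"], target)] = float(row["mean_ct"])
    return lookup


def pfaffl_ratio(kept: pd.DataFrame,
                 efficiencies: Mapping[str, float],
                 goi: str,
                 reference_genes: Sequence[str],
                 control_sample: str,
                 direction: str = "control_minus_sample") -> pd.DataFrame:
    """Efficiency-corrected expression ratio of `goi` per sample.

    RQ_g = E_g ** dCt_g with dCt = Ct_control - Ct_sample (canonical
    direction: higher expression gives a ratio above 1; set `direction`
    to "sample_minus_control" to flip). The ratio divides the RQ of the
    gene of interest by the geometric mean RQ of the reference genes.
    Samples lacking a QC-passed Ct for the gene of interest or any
    reference (or a missing control measurement) yield NA with a
    reason.
    """
    if direction not in ("control_minus_sample", "sample_minus_control"):
        raise ValueError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == "control_minus_sample" else -1.0
    lookup = _mean_ct_lookup(kept)
    samples = sorted({s for s, _ in lookup})
    targets = [goi] + list(reference_genes)
    for t in targets:
        if t not in efficiencies:
            raise ValueError(f"no efficiency supplied for target {t!r}")
    rows = []
    for sample in samples:
        reason = ""
        ratio = math.nan
        missing_ctrl = [t for t in targets if (control_sample, t) not in lookup]
        missing_here = [t for t in targets if (sample, t) not in lookup]
        if missing_ctrl:
            reason = f"control measurement missing for {missing_ctrl}"
        elif missing_here:
            reason = f"sample measurement missing for {missing_here}"
        else:
            def rq(target: str) -> float:
                dct = lookup[(control_sample, target)] - lookup[(sample, target)]
                return efficiencies[target] ** (sign * dct)
            rq_refs = [rq(r) for r in reference_genes]
            geo = float(np.exp(np.mean(np.log(rq_refs))))
            ratio = rq(goi) / geo
        rows.append({"sample_id": sample, "target": goi, "ratio": ratio,
                     "reason": reason})
    return pd.DataFrame(rows)


def delta_ct_matrix(kept: pd.DataFrame,
                    reference_genes: Sequence[str],
                    sentinel: float = CT_SENTINEL) -> pd.DataFrame:
    """Delta-Ct of every target against the reference-gene geometric mean.

    dCt(sample, target) = mean Ct(target) - geometric mean of the
    reference genes' mean Cts in the same sample. Targets or references
    at the sentinel, or samples with any reference missing, propagate
    to NA. Rows are samples, columns targets.
    """
    lookup = _mean_ct_lookup(kept)
    samples = sorted({s for s, _ in lookup})
    targets = sorted({t for _, t in lookup})
    out = pd.DataFrame(index=samples, columns=targets, dtype=float)
    out.index.name = "sample_id"
    for sample in samples:
        ref_cts = [lookup.get((sample, r), math.nan) for r in reference_genes]
        if any(math.isnan(v) or v >= sentinel for v in ref_cts):
            continue  # whole row stays NA
        geo_ref = float(np.exp(np.mean(np.log(ref_cts))))
        for target in targets:
            ct = lookup.get((sample, target), math.nan)
            if math.isnan(ct) or ct >= sentinel:
                continue
            out.loc[sample, target] = ct - geo_ref
    return out
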