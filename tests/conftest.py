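import pytest

from grass_si.markers import Marker, MarkerMap


@pytest.fixture
def four_marker_map() -> MarkerMap:
    """Four markers straddling the locus, with physical positions."""
    return MarkerMap(
        markers=(
            Marker("m1", -2.0, contig="c1", bp=100),
            Marker("m2", -1.0, contig="c1", bp=500),
            Marker("m3", 1.0, contig="c1", bp=900),
            Marker("m4", 2.0, contig="c1", bp=1300),
        ),
        locus_cm=0.0, locus_name="Z", contig="c1",
        contig_length=2000, locus_bp=700,
    )


def finemap_screen_map() -> MarkerMap:
    """The 8-marker screening panel spanning +/-2 cM around the locus.

    The two inner markers lie within the co-segregating region
    (1e-5 cM from the locus: recombination there is suppressed far
    below one event per ten thousand gametes, matching a region that
    shows zero recombinants in a screen of this size); physical
    positions span a ~100 kb contig with the locus at 50 kb.
    """
    markers = (
        Marker("m1", -2.0, contig="bac", bp=5_000),
        Marker("m2", -1.0, contig="bac", bp=20_000),
        Marker("m3", -0.1, contig="bac", bp=38_000),
        Marker("m4", -1e-5, contig="bac", bp=45_000),
        Marker("m5", 1e-5, contig="bac", bp=55_000),
        Marker("m6", 0.1, contig="bac", bp=62_000),
        Marker("m7", 1.0, contig="bac", bp=80_000),
        Marker("m8", 2.0, contig="bac", bp=95_000),
    )
    return MarkerMap(markers=markers, locus_cm=0.0, locus_name="Z",
                     contig="bac", contig_length=100_000, locus_bp=50_000)


@pytest.fixture
def screen_map() -> MarkerMap:
    return finemap_screen_map()
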