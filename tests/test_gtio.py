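"""I/O round trips and elementary genotype transforms."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleogt import (
    MISSING,
    GeneticMap,
    IbdSegment,
    Interval,
    SampleCallset,
    apply_gp_filter,
    classify_substitution,
    maf_tranche,
    make_site_table,
    read_bed,
    read_ibd_table,
    read_map,
    read_vcf,
    write_bed,
    write_ibd_table,
    write_map,
    write_vcf,
)
from paleogt.gtio import maf_tranches
from paleogt.sim import ErrorModel, simulate_imputed


# ---------------------------------------------------------------------------
# substitution classes and MAF tranches
# ---------------------------------------------------------------------------

def test_substitution_classes_exhaustive():
    """All 12 ordered allele pairs: 4 transitions, 8 transversions."""
    pairs = [(r, a) for r, a in itertools.permutations("ACGT", 2)]
    classes = [classify_substitution(r, a) for r, a in pairs]
    assert classes.count("transition") == 4
    assert classes.count("transversion") == 8
    assert classify_substitution("A", "G") == "transition"
    assert classify_substitution("A", "C") == "transversion"
    with pytest.raises(ValueError):
        classify_substitution("A", "N")


@pytest.mark.parametrize(
    "maf,label",
    [
        (0.07, "(5,10]"),
        (0.05, "(2,5]"),  # right-closed: exactly 5% belongs to (2,5]
        (0.0, "monomorphic"),
        (0.005, "(0,1]"),
        (0.5, "(20,50]"),
        (0.2, "(10,20]"),
    ],
)
def test_maf_tranche_assignment(maf, label):
    assert maf_tranche(maf) == label


@given(st.floats(min_value=1e-9, max_value=0.5, allow_nan=False))
@settings(max_examples=200, deadline=None)
def test_maf_tranche_partitions_unit_interval(maf):
    """Every maf in (0, 0.5] maps to exactly one tranche; vectorised and
    scalar versions agree."""
    label = maf_tranche(maf)
    assert label != "monomorphic"
    assert maf_tranches(np.array([maf]))[0] == label


def test_maf_tranche_rejects_out_of_range():
    with pytest.raises(ValueError):
        maf_tranche(0.6)
    with pytest.raises(ValueError):
        maf_tranche(-0.01)


# ---------------------------------------------------------------------------
# GP filtering
# ---------------------------------------------------------------------------

def _callset_with_gp(tiny_sites, dosages, gps):
    return SampleCallset("s1", tiny_sites, np.array(dosages, dtype=np.int8), np.array(gps))


def test_gp_filter_threshold_and_argmax_guard(tiny_sites):
    cs = _callset_with_gp(
        tiny_sites,
        [1, 1, 0, 2],
        [
            (0.2, 0.5, 0.3),       # max 0.5 < 0.99 -> missing
            (0.005, 0.99, 0.005),  # boundary inclusive -> kept
            (0.01, 0.98, 0.01),    # argmax (het) != dosage 0 -> missing
            (0.0, 0.0, 1.0),
        ],
    )
    out = apply_gp_filter(cs, 0.99)
    assert list(out.dosage) == [MISSING, 1, MISSING, 2]


def test_gp_filter_idempotent_and_monotone(small_panel):
    truth = SampleCallset(
        "t", small_panel.sites, (small_panel.haplotypes[0] + small_panel.haplotypes[1]).astype(np.int8)
    )
    imp = simulate_imputed(truth, ErrorModel(), 0.5, seed=5)
    counts = []
    for thr in (0.7, 0.8, 0.9, 0.95, 0.99):
        once = apply_gp_filter(imp, thr)
        twice = apply_gp_filter(once, thr)
        assert np.array_equal(once.dosage, twice.dosage)
        counts.append(int((once.dosage != MISSING).sum()))
    assert counts == sorted(counts, reverse=True)


def test_gp_filter_drops_gp_free_calls(tiny_sites):
    cs = SampleCallset("s", tiny_sites, np.array([0, 1, 2, 0], dtype=np.int8))
    assert (apply_gp_filter(cs, 0.7).dosage == MISSING).all()
    assert list(apply_gp_filter(cs, 0.0).dosage) == [0, 1, 2, 0]


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

def test_map_linear_interpolation_and_extrapolation():
    gmap = GeneticMap({"chr1": ([0, 1_000_000], [0.0, 1.0])})
    assert gmap.cm("chr1", 500_000) == pytest.approx(0.5)
    assert gmap.cm("chr1", 2_000_000) == pytest.approx(1.0)  # constant beyond end
    with pytest.raises(KeyError):
        gmap.cm("chrX", 1)


@given(
    st.lists(st.integers(min_value=0, max_value=10**8), min_size=2, max_size=8, unique=True),
    st.lists(st.floats(min_value=0, max_value=10, allow_nan=False), min_size=8, max_size=8),
    st.lists(st.integers(min_value=0, max_value=2 * 10**8), min_size=2, max_size=30),
)
@settings(max_examples=100, deadline=None)
def test_map_monotone_over_sorted_queries(anchors_bp, deltas, queries):
    bp = sorted(anchors_bp)
    cm = np.cumsum(deltas[: len(bp)])
    gmap = GeneticMap({"c": (np.array(bp, float), cm)})
    vals = [gmap.cm("c", q) for q in sorted(queries)]
    assert all(a <= b + 1e-9 for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# file round trips
# ---------------------------------------------------------------------------

def test_vcf_round_trip(tmp_path, small_panel):
    rng = np.random.default_rng(3)
    sites = small_panel.sites
    n = len(sites)
    dos = rng.integers(0, 3, size=n).astype(np.int8)
    dos[rng.random(n) < 0.05] = MISSING
    gp = np.full((n, 3), 0.01)
    for i in range(n):
        gp[i, dos[i] if dos[i] != MISSING else 1] = 0.98
    cs = SampleCallset("sampleA", sites, dos, gp)
    path = str(tmp_path / "rt.vcf")
    write_vcf(sites, [cs], path, small_panel.chrom_lengths)
    sites2, callsets2 = read_vcf(path)
    assert len(sites2) == n
    np.testing.assert_array_equal(callsets2[0].dosage, dos)
    np.testing.assert_allclose(callsets2[0].gp, gp, atol=1e-3)
    np.testing.assert_allclose(sites2["alt_freq"], sites["alt_freq"], atol=1e-6)


def test_vcf_trivial_encodings(tmp_path, tiny_sites):
    cs = SampleCallset(
        "s1", tiny_sites, np.array([1, 2, MISSING, 0], dtype=np.int8),
        np.array([(0.01, 0.98, 0.01)] * 4),
    )
    path = str(tmp_path / "enc.vcf")
    write_vcf(tiny_sites, [cs], path)
    text = open(path).read()
    assert "0/1:0.01,0.98,0.01" in text
    assert "./." in text
    _, (back,) = read_vcf(path)
    assert list(back.dosage) == [1, 2, MISSING, 0]


def test_vcf_skips_multiallelic(tmp_path):
    path = tmp_path / "multi.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        "##contig=<ID=chr1,length=1000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
        "chr1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\n"
        "chr1\t200\t.\tC\tA,T\t.\t.\t.\tGT\t0/1\t0/0\n"
        "chr1\t300\t.\tG\tT\t.\t.\t.\tGT\t1/1\t./.\n"
    )
    sites, callsets = read_vcf(str(path))
    assert len(sites) == 2
    assert sites.attrs["n_skipped"] == 1
    assert list(callsets[0].dosage) == [1, 2]
    assert list(callsets[1].dosage) == [2, MISSING]


def test_empty_callset_list_gives_header_only_vcf(tmp_path, tiny_sites):
    path = str(tmp_path / "empty.vcf")
    write_vcf(tiny_sites.iloc[:0], [], path)
    lines = [l for l in open(path) if not l.startswith("#")]
    assert lines == []


def test_bed_and_map_and_ibd_round_trips(tmp_path):
    bed = tmp_path / "x.bed"
    bed.write_text("chr1\t0\t500000\nchr2\t100\t200\tname\n")
    ivs = read_bed(str(bed))
    assert ivs[0] == Interval("chr1", 0, 500000)
    assert ivs[1].payload == "name"
    write_bed(ivs, str(tmp_path / "y.bed"))
    assert read_bed(str(tmp_path / "y.bed")) == ivs

    gmap = GeneticMap({"chr1": ([0, 10_000_000], [0.0, 10.0])})
    write_map(gmap, str(tmp_path / "m.txt"))
    back = read_map(str(tmp_path / "m.txt"))
    assert back.cm("chr1", 5_000_000) == pytest.approx(5.0)

    segs = [IbdSegment("a", "b", "chr1", 100, 9000, 4.2)]
    write_ibd_table(segs, str(tmp_path / "ibd.tsv"))
    back_segs = read_ibd_table(str(tmp_path / "ibd.tsv"))
    assert back_segs[0].lod == pytest.approx(4.2)
    assert back_segs[0].start_bp == 100 and back_segs[0].end_bp == 9000


def test_malformed_lines_report_line_numbers(tmp_path):
    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t0\t100\nchr1\tnotanint\t5\n")
    with pytest.raises(ValueError, match=":2"):
        read_bed(str(bad))
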