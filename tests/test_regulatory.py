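"""Peak handling, motif scanning, TF->gene assignment and enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom, fisher_exact

from polyflow.exceptions import InputError, ParseError
from polyflow import io as pio
from polyflow.regulatory import (
    PWM,
    build_tf_gene_network,
    matches_to_frame,
    merge_peak_sets,
    scan_motifs,
    tf_enrichment,
)
from helpers import brute_force_scan, mask_union


def _peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def test_disjoint_sets_concatenate():
    a = _peaks([("chr1", 0, 10), ("chr1", 50, 60)])
    b = _peaks([("chr2", 5, 15)])
    merged = merge_peak_sets([a, b])
    assert len(merged) == 3


def test_overlapping_and_bookended_intervals_merge():
    merged = merge_peak_sets([_peaks([("chr1", 100, 200), ("chr1", 150, 250)])])
    assert merged.values.tolist() == [["chr1", 100, 250]]
    merged = merge_peak_sets([_peaks([("chr1", 100, 200), ("chr1", 200, 300)])])
    assert merged.values.tolist() == [["chr1", 100, 300]]


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_merge_matches_per_base_mask_and_is_idempotent(seed):
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(3):
        starts = rng.integers(0, 2000, size=rng.integers(1, 30))
        rows = [("chr1", int(s), int(s + rng.integers(1, 80))) for s in starts]
        sets.append(_peaks(rows))
    merged = merge_peak_sets(sets)
    oracle = mask_union(sets)
    pd.testing.assert_frame_equal(merged.reset_index(drop=True), oracle)
    again = merge_peak_sets([merged] + sets[::-1])
    pd.testing.assert_frame_equal(again, merged)


def test_thousand_random_intervals_match_mask_oracle():
    rng = np.random.default_rng(123)
    rows = [
        (f"chr{rng.integers(1, 4)}", int(s), int(s + rng.integers(1, 120)))
        for s in rng.integers(0, 50_000, size=1000)
    ]
    sets = [_peaks(rows[:500]), _peaks(rows[500:])]
    pd.testing.assert_frame_equal(merge_peak_sets(sets), mask_union(sets))


def test_malformed_bed_reports_line_number(tmp_path):
    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t10\t20\nchr1\t30\t25\n")
    with pytest.raises(ParseError, match="line 2"):
        pio.read_bed(bad)


def test_pwm_validation_names_bad_position():
    matrix = np.full((5, 4), 0.25)
    matrix[2] = [0.4, 0.3, 0.1, 0.1]  # sums to 0.9
    with pytest.raises(InputError, match="position 3"):
        PWM(tf="BAD", matrix=matrix)


def _consensus_pwm(tf, consensus, threshold=0.85, strength=0.97):
    matrix = np.full((len(consensus), 4), (1 - strength) / 3)
    for i, base in enumerate(consensus):
        matrix[i, "ACGT".index(base)] = strength
    return PWM(tf=tf, matrix=matrix, threshold=threshold)


def test_consensus_scores_one_at_planted_offset():
    pwm = _consensus_pwm("TF1", "ACGTACGT", threshold=0.99)
    genome = {"chr1": "TTTTT" + "ACGTACGT" + "TTTTTTT"}
    peaks = _peaks([("chr1", 0, 20)])
    matches = scan_motifs(genome, peaks, [pwm])
    plus = [m for m in matches if m.strand == "+"]
    assert len(plus) == 1
    assert plus[0].start == 5 and plus[0].score == pytest.approx(1.0)


def test_sequence_shorter_than_motif_yields_no_matches():
    pwm = _consensus_pwm("TF1", "ACGTACGT")
    assert scan_motifs({"chr1": "ACG"}, _peaks([("chr1", 0, 3)]), [pwm]) == []


def test_peak_past_chromosome_end_clipped_with_warning():
    pwm = _consensus_pwm("TF1", "ACGTACGT", threshold=0.99)
    genome = {"chr1": "AACGTACGTA"}
    with pytest.warns(UserWarning, match="clipped"):
        matches = scan_motifs(genome, _peaks([("chr1", 0, 50)]), [pwm])
    assert [m.start for m in matches if m.strand == "+"] == [1]


def test_scan_matches_exhaustive_window_oracle():
    rng = np.random.default_rng(7)
    for rep in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        matrix = rng.dirichlet(np.full(4, 0.6), size=8)
        pwm = PWM(tf="R", matrix=matrix, threshold=0.8)
        got = {
            (m.start, m.strand, round(m.score, 9))
            for m in scan_motifs({"c": seq}, _peaks([("c", 0, 300)]), [pwm])
        }
        assert got == brute_force_scan(seq, pwm)


def test_reverse_complemented_genome_gives_mirrored_matches():
    rng = np.random.default_rng(9)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    pwm = _consensus_pwm("TF1", "ACGTAAGG", threshold=0.8)
    fwd = scan_motifs({"c": seq}, _peaks([("c", 0, 400)]), [pwm])
    rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    rev = scan_motifs({"c": rc}, _peaks([("c", 0, 400)]), [pwm])
    flip = {"+": "-", "-": "+"}
    mirrored = {(400 - m.end, flip[m.strand], round(m.score, 9)) for m in rev}
    assert {(m.start, m.strand, round(m.score, 9)) for m in fwd} == mirrored


def _tss(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])


def test_match_outside_window_assigns_no_edge():
    matches = matches_to_frame([])
    from polyflow.regulatory import MotifMatch

    m = MotifMatch("TF1", "chr1", 5996, 6004, "+", 0.9)  # midpoint 6000 from TSS 0
    edges = build_tf_gene_network([m], _tss([("G1", "chr1", 0, "+")]), window=5000)
    assert edges.empty


def test_best_scoring_match_sets_edge_weight():
    from polyflow.regulatory import MotifMatch

    ms = [
        MotifMatch("TF1", "chr1", 100, 108, "+", 0.80),
        MotifMatch("TF1", "chr1", 300, 308, "-", 0.95),
    ]
    edges = build_tf_gene_network(ms, _tss([("G1", "chr1", 500, "+")]))
    assert edges.values.tolist() == [["TF1", "G1", 0.95]]


def test_edge_assignment_matches_quadratic_oracle():
    rng = np.random.default_rng(21)
    from polyflow.regulatory import MotifMatch

    tss = _tss(
        [(f"G{i}", f"chr{rng.integers(1, 3)}", int(rng.integers(0, 100_000)), "+") for i in range(30)]
    )
    matches = [
        MotifMatch(
            f"TF{rng.integers(1, 5)}",
            f"chr{rng.integers(1, 3)}",
            int(s),
            int(s) + 8,
            "+",
            float(rng.uniform(0.8, 1.0)),
        )
        for s in rng.integers(0, 100_000, size=200)
    ]
    edges = build_tf_gene_network(matches, tss, window=5000)
    expected = {}
    for m in matches:
        mid = (m.start + m.end) / 2
        for _, g in tss.iterrows():
            if g["chrom"] == m.chrom and abs(mid - g["tss"]) <= 5000:
                key = (m.tf, g["gene"])
                expected[key] = max(expected.get(key, 0.0), m.score)
    got = {(r["tf"], r["gene"]): r["weight"] for _, r in edges.iterrows()}
    assert got == expected
    assert all(0 < w <= 1 for w in got.values())


def test_ubiquitous_tf_is_not_enriched():
    genes = [f"G{i}" for i in range(100)]
    edges = pd.DataFrame({"tf": "TF1", "gene": genes, "weight": 0.9})
    de = set(genes[:30])
    result = tf_enrichment(edges, de, set(genes), min_de_promoters=10)
    assert result.loc[0, "odds_ratio"] == pytest.approx(1.0, abs=1e-9) or np.isnan(
        result.loc[0, "odds_ratio"]
    )
    assert result.loc[0, "p_value"] == pytest.approx(1.0)


def test_fisher_p_equals_hypergeometric_tail_sum():
    # table (a=30, b=70, c=10, d=90): one-sided 'greater' tail
    a, b, c, d = 30, 70, 10, 90
    oracle = hypergeom.sf(a - 1, a + b + c + d, a + c, a + b)
    _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    edges = pd.DataFrame(
        {"tf": "T", "gene": [f"D{i}" for i in range(a)] + [f"N{i}" for i in range(c)], "weight": 0.9}
    )
    de = {f"D{i}" for i in range(a + b)}
    background = de | {f"N{i}" for i in range(c + d)}
    result = tf_enrichment(edges, de, background, min_de_promoters=5)
    assert result.loc[0, "p_value"] == pytest.approx(oracle, rel=1e-9)
    assert p == pytest.approx(oracle, rel=1e-9)


def test_planted_tfs_enriched_in_scenario(small_scenario):
    """Path-terminal TFs (whose planted targets are DE by construction) show
    stronger enrichment on average than TFs with only random targets."""
    sc = small_scenario
    de = set(sc.truth.de_genes)
    background = set(sc.config.genes)
    result = tf_enrichment(sc.regulatory_edges, de, background, min_de_promoters=1)
    planted_tfs = {p[-1] for p in sc.truth.paths}
    by_tf = result.set_index("tf")["p_value"]
    planted_p = by_tf[by_tf.index.isin(planted_tfs)]
    other_p = by_tf[~by_tf.index.isin(planted_tfs)]
    assert planted_p.mean() < other_p.mean()
    assert by_tf.idxmin() in planted_tfs
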