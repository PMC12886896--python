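"""Metagene extraction, TSS scoring and the cumulative-80% selection rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from germ_epimem.core_io import EnrichmentTrack, Gene, GenomeAnnotation, GenomicInterval
from germ_epimem.metagene import (
    average_profile,
    build_score_table,
    compare_scores,
    metagene_matrix,
    select_enriched_genes,
    tss_window_score,
)


def flat_track(value, n_bins=400, bin_size=10):
    return EnrichmentTrack(bin_size, {"c": np.full(n_bins, float(value))})


def gene(gid, start, end, strand="+"):
    return Gene(gid, GenomicInterval("c", start, end, strand))


class TestMetageneMatrix:
    def test_flat_track_fills_every_cell(self):
        ann = GenomeAnnotation([gene("g1", 2000, 2500)])
        mat = metagene_matrix(flat_track(1.5), ann)
        assert np.all(mat.values == 1.5)

    def test_strand_flip_mirrors_rows(self):
        ramp = EnrichmentTrack(10, {"c": np.arange(400, dtype=float)})
        # a plus gene and a minus gene whose TSS sits at the same bin center
        ann = GenomeAnnotation(
            [gene("plus", 2000, 2500, "+"), gene("minus", 1501, 2001, "-")]
        )
        mat = metagene_matrix(ramp, ann)
        np.testing.assert_array_equal(mat.values[0], mat.values[1][::-1])

    def test_chromosome_edge_marked_missing(self):
        ann = GenomeAnnotation([gene("g1", 30, 530)])
        mat = metagene_matrix(flat_track(2.0), ann, upstream=1000, downstream=1000)
        row = mat.values[0]
        assert np.isnan(row[:97]).all()  # bins before the chromosome start
        assert np.isfinite(row[100:]).all()

    def test_average_profile_ignores_missing(self):
        ann = GenomeAnnotation([gene("g1", 30, 530), gene("g2", 2000, 2500)])
        mat = metagene_matrix(flat_track(3.0), ann)
        profile = average_profile(mat)
        np.testing.assert_allclose(profile, 3.0)

    def test_two_gene_average(self):
        ann = GenomeAnnotation([gene("g1", 2000, 2500), gene("g2", 2000, 2500)])
        mat = metagene_matrix(flat_track(1.0), ann)
        mat.values[0, :] = 0.0
        mat.values[1, :] = 2.0
        np.testing.assert_allclose(average_profile(mat), 1.0)


class TestTssWindowScore:
    def test_uniform_track_scores_uniform(self):
        ann = GenomeAnnotation([gene("g1", 2000, 2500), gene("g2", 3000, 3500, "-")])
        scores = tss_window_score(flat_track(0.7), ann)
        assert set(scores.round(12)) == {0.7}

    def test_brute_force_window_mean(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=400)
        track = EnrichmentTrack(10, {"c": values})
        tss = 2000
        ann = GenomeAnnotation([gene("g1", tss, tss + 500)])
        halfwidth = 500
        expected = np.mean(
            [
                values[b]
                for b in range(400)
                if b * 10 < tss + halfwidth and (b + 1) * 10 > tss - halfwidth
            ]
        )
        assert tss_window_score(track, ann, halfwidth)["g1"] == pytest.approx(expected)

    def test_strand_flip_preserves_score_window_symmetric(self):
        rng = np.random.default_rng(10)
        track = EnrichmentTrack(10, {"c": rng.normal(size=400)})
        # same TSS bin: plus gene TSS=2000 -> bin 200; minus gene with
        # end-1 = 2000 has the same window
        plus = GenomeAnnotation([gene("g", 2000, 2500, "+")])
        minus = GenomeAnnotation([gene("g", 1501, 2001, "-")])
        s_plus = tss_window_score(track, plus)["g"]
        s_minus = tss_window_score(track, minus)["g"]
        assert s_plus == pytest.approx(s_minus)


class TestScoreTable:
    def test_identical_tracks_zero_delta(self):
        ann = GenomeAnnotation([gene("g1", 2000, 2500), gene("g2", 3000, 3500)])
        t = flat_track(1.0)
        table = build_score_table(t, t, ann)
        assert (table["delta"] == 0).all()
        assert len(table) == 2

    def test_constant_shift_appears_in_delta(self):
        ann = GenomeAnnotation([gene("g1", 2000, 2500)])
        table = build_score_table(flat_track(1.0), flat_track(2.0), ann)
        assert table["delta"]["g1"] == pytest.approx(1.0)


def minimal_prefix_oracle(deltas: dict[str, float], fraction: float) -> list[str]:
    """Exhaustive search for the minimal delta-ranked prefix."""
    positive = {g: d for g, d in deltas.items() if d > 0}
    if not positive:
        return []
    ranked = sorted(positive, key=lambda g: (-positive[g], g))
    total = sum(positive.values())
    cum = 0.0
    out = []
    for g in ranked:
        out.append(g)
        cum += positive[g]
        if cum >= fraction * total - 1e-12 * max(1.0, abs(fraction * total)):
            return out
    return out


def as_table(deltas):
    return pd.DataFrame(
        {
            "score_wt": 0.0,
            "score_mut": list(deltas.values()),
            "delta": list(deltas.values()),
        },
        index=pd.Index(list(deltas.keys()), name="gene_id"),
    )


class TestSelection:
    def test_worked_example(self):
        deltas = {"A": 5.0, "B": 3.0, "C": 1.0, "D": 1.0, "E": -2.0}
        assert select_enriched_genes(as_table(deltas)) == ["A", "B"]

    def test_tie_example_both_orders(self):
        for order in itertools.permutations(["A", "B", "C"]):
            deltas = {g: {"A": 4.0, "B": 4.0, "C": 2.0}[g] for g in order}
            assert set(select_enriched_genes(as_table(deltas))) == {"A", "B"}

    def test_no_positive_deltas_empty(self):
        assert select_enriched_genes(as_table({"A": -1.0, "B": 0.0})) == []

    def test_matches_exhaustive_oracle_on_random_tables(self):
        rng = np.random.default_rng(77)
        for _ in range(1000):
            n = int(rng.integers(1, 21))
            deltas = {
                f"g{i}": float(np.round(rng.normal(), 3)) for i in range(n)
            }
            fraction = float(rng.uniform(0.05, 1.0))
            got = select_enriched_genes(as_table(deltas), fraction=fraction)
            expected = minimal_prefix_oracle(deltas, fraction)
            assert got == expected, (deltas, fraction)

    def test_minimality_dropping_last_breaks_threshold(self):
        rng = np.random.default_rng(78)
        for _ in range(200):
            n = int(rng.integers(2, 15))
            deltas = {f"g{i}": float(rng.normal()) for i in range(n)}
            table = as_table(deltas)
            selected = select_enriched_genes(table, fraction=0.8)
            if len(selected) < 2:
                continue
            total = table.loc[table["delta"] > 0, "delta"].sum()
            partial = table.loc[selected[:-1], "delta"].sum()
            assert partial < 0.8 * total

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(79)
        for _ in range(200):
            deltas = {f"g{i}": float(rng.normal()) for i in range(12)}
            f1, f2 = sorted(rng.uniform(0.05, 1.0, size=2))
            s1 = select_enriched_genes(as_table(deltas), fraction=float(f1))
            s2 = select_enriched_genes(as_table(deltas), fraction=float(f2))
            assert set(s1) <= set(s2)


class TestCompareScores:
    def test_equal_columns_give_null(self):
        table = as_table({"A": 0.0, "B": 0.0})
        table["score_wt"] = [1.0, 2.0]
        table["score_mut"] = [1.0, 2.0]
        res = compare_scores(table)
        assert res["t_statistic"] == 0.0
        assert res["p_value"] == 1.0

    def test_welch_hand_example(self):
        table = pd.DataFrame(
            {"score_wt": [0.0, 1.0], "score_mut": [10.0, 11.0]},
            index=pd.Index(["a", "b"], name="gene_id"),
        )
        res = compare_scores(table)
        assert res["t_statistic"] == pytest.approx(-14.142, abs=1e-3)
        assert res["df"] == pytest.approx(2.0)
        # p from the t distribution directly
        expected_p = 2 * stats.t.sf(14.142135, df=2)
        assert res["p_value"] == pytest.approx(expected_p, rel=1e-4)

    def test_location_invariance(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(
            {"score_wt": rng.normal(size=30), "score_mut": rng.normal(1, 1, size=30)},
            index=pd.Index([f"g{i}" for i in range(30)], name="gene_id"),
        )
        base = compare_scores(table)
        shifted = compare_scores(table + 5.0)
        assert base["t_statistic"] == pytest.approx(shifted["t_statistic"])
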