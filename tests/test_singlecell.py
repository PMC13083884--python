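"""Single-cell QC filters, UMI dedup, Tn5 shift, TSS score, pseudobulk
accessibility and differential classes."""

import numpy as np
import pandas as pd
import pytest

from poisedpol.annotation import GeneModel
from poisedpol.singlecell import (
    dedup_umi,
    differential_classes,
    pseudobulk_accessibility,
    qc_filter_atac,
    qc_filter_rna,
    tn5_shift,
    tss_enrichment_score,
)


def cells(rows):
    return pd.DataFrame(rows).set_index("cell_barcode")


class TestQcFilters:
    def test_rna_thresholds(self):
        table = cells([
            {"cell_barcode": "keep", "n_genes_detected": 600,
             "total_umis": 1000, "mito_umis": 20},
            {"cell_barcode": "few_genes", "n_genes_detected": 499,
             "total_umis": 1000, "mito_umis": 10},
            {"cell_barcode": "mito_at_5pct", "n_genes_detected": 600,
             "total_umis": 1000, "mito_umis": 50},
            {"cell_barcode": "no_umis", "n_genes_detected": 600,
             "total_umis": 0, "mito_umis": 0},
        ])
        assert list(qc_filter_rna(table).index) == ["keep"]

    def test_atac_thresholds(self):
        table = cells([
            {"cell_barcode": "keep", "n_fragments": 1500, "tss_score": 11.3},
            {"cell_barcode": "few_frags", "n_fragments": 999, "tss_score": 10.0},
            {"cell_barcode": "low_score", "n_fragments": 1500, "tss_score": 3.9},
        ])
        assert list(qc_filter_atac(table).index) == ["keep"]

    def test_filters_are_idempotent(self, rng):
        table = cells([
            {"cell_barcode": f"c{i}",
             "n_genes_detected": int(rng.integers(0, 1200)),
             "total_umis": int(rng.integers(1, 5000)),
             "mito_umis": int(rng.integers(0, 200)),
             "n_fragments": int(rng.integers(0, 3000)),
             "tss_score": float(rng.uniform(0, 15))}
            for i in range(50)
        ])
        once = qc_filter_rna(table)
        assert qc_filter_rna(once).equals(once)
        once_atac = qc_filter_atac(table)
        assert qc_filter_atac(once_atac).equals(once_atac)


class TestTn5Shift:
    def frags(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                           "cell_barcode", "umi"])

    def test_plus_minus_shift(self):
        out = tn5_shift(self.frags([("c", 100, 200, "b1", "u1")]))
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (104, 195)

    def test_degenerate_fragment_dropped(self):
        out = tn5_shift(self.frags([("c", 100, 109, "b1", "u1")]))
        assert len(out) == 0

    def test_double_shift_refused(self):
        out = tn5_shift(self.frags([("c", 100, 200, "b1", "u1")]))
        with pytest.raises(ValueError, match="already"):
            tn5_shift(out)


class TestDedupUmi:
    def frags(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                           "cell_barcode", "umi"])

    def test_identical_keys_collapse(self):
        out = dedup_umi(self.frags([("c", 1, 10, "b", "u")] * 2))
        assert len(out) == 1

    def test_same_umi_different_coordinates_kept(self):
        out = dedup_umi(self.frags([("c", 1, 10, "b", "u"), ("c", 5, 15, "b", "u")]))
        assert len(out) == 2

    def test_same_coordinates_different_cells_kept(self):
        out = dedup_umi(self.frags([("c", 1, 10, "b1", "u"), ("c", 1, 10, "b2", "u")]))
        assert len(out) == 2

    def test_size_equals_distinct_key_count(self, rng):
        rows = [("c", int(rng.integers(0, 20)), int(rng.integers(21, 40)),
                 f"b{rng.integers(0, 3)}", f"u{rng.integers(0, 3)}")
                for _ in range(200)]
        df = self.frags(rows)
        expected = len({tuple(r) for r in rows})
        assert len(dedup_umi(df)) == expected


class TestTssEnrichmentScore:
    def test_uniform_insertions_score_near_one(self, rng):
        chrom_len = 200_000
        starts = rng.integers(0, chrom_len - 100, 10_000)
        frags = pd.DataFrame({"chrom": "c", "start": starts, "end": starts + 100,
                              "cell_barcode": "b", "umi": "u"})
        tss = [("c", int(p)) for p in rng.integers(3000, chrom_len - 3000, 40)]
        score = tss_enrichment_score(frags, tss)
        assert 0.8 <= score <= 1.2

    def test_all_insertions_at_tss_scores_high(self):
        tss = [("c", 5000)]
        frags = pd.DataFrame({"chrom": "c", "start": [4990] * 50,
                              "end": [5010] * 50, "cell_barcode": "b", "umi": "u"})
        assert tss_enrichment_score(frags, tss) > 4

    def test_no_fragments_scores_zero(self):
        frags = pd.DataFrame(columns=["chrom", "start", "end", "cell_barcode", "umi"])
        assert tss_enrichment_score(frags, [("c", 100)]) == 0.0

    def test_no_tss_errors(self):
        frags = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10],
                              "cell_barcode": "b", "umi": "u"})
        with pytest.raises(ValueError):
            tss_enrichment_score(frags, [])


class TestPseudobulkAccessibility:
    def test_single_spanning_fragment_per_million(self):
        gene = GeneModel("g", "c", 5000, 8000, "+")
        frags = pd.DataFrame({
            "chrom": ["c"] * 10**6,
            "start": [0] * (10**6 - 1) + [4700],
            "end": [10] * (10**6 - 1) + [5300],
            "cell_barcode": ["b0"] * 10**6,
            "umi": "u",
        })
        labels = pd.Series({"b0": "SpG"})
        out = pseudobulk_accessibility(frags, labels, gene, {"c": 10_000})
        assert out["SpG"].value == pytest.approx(1.0)

    def test_per_million_invariance_under_duplication(self):
        gene = GeneModel("g", "c", 500, 900, "+")
        base = pd.DataFrame({
            "chrom": ["c"] * 100,
            "start": list(range(300, 700, 4)),
            "end": [s + 80 for s in range(300, 700, 4)],
            "cell_barcode": ["b0"] * 100,
            "umi": [f"u{i}" for i in range(100)],
        })
        labels = pd.Series({"b0": "t"})
        v1 = pseudobulk_accessibility(base, labels, gene, {"c": 2000})["t"].value
        doubled = pd.concat([base, base], ignore_index=True)
        v2 = pseudobulk_accessibility(doubled, labels, gene, {"c": 2000})["t"].value
        assert v1 == pytest.approx(v2)

    def test_empty_cell_type_missing(self):
        gene = GeneModel("g", "c", 100, 400, "+")
        frags = pd.DataFrame({"chrom": ["c"], "start": [100], "end": [200],
                              "cell_barcode": ["b0"], "umi": "u"})
        labels = pd.Series({"b0": "a", "b1": "empty"})
        out = pseudobulk_accessibility(frags, labels, gene, {"c": 1000})
        assert out["empty"] is None


class TestDifferentialClasses:
    def counts(self, means, n_cells, rng, prefix):
        mat = rng.poisson(np.asarray(means)[:, None], (len(means), n_cells))
        return pd.DataFrame(mat, index=[f"g{i}" for i in range(len(means))],
                            columns=[f"{prefix}{j}" for j in range(n_cells)])

    def test_identical_groups_all_unchanged(self, rng):
        a = self.counts([5] * 50, 30, rng, "a")
        res = differential_classes(a, a.copy())
        assert all(r.klass == "unchanged" for r in res)

    def test_true_threefold_increase_detected(self):
        """Genes with a true 3x increase (Poisson means 15 vs 5) embedded in
        a mostly-null library are classified up in >= 90% of cases."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            means_b = np.full(200, 5.0)
            means_a = means_b.copy()
            means_a[:20] *= 3  # the deregulated subset
            a = self.counts(means_a, 200, rng, "a")
            b = self.counts(means_b, 200, rng, "b")
            res = differential_classes(a, b)
            up = [r.klass == "up" for r in res[:20]]
            hits += np.mean(up) >= 0.9
        assert hits >= 9

    def test_fc_without_significance_is_unchanged(self):
        # constructed: fold change 1.9 with tiny q must stay unchanged
        from poisedpol.singlecell import DifferentialResult

        r = DifferentialResult("g", 1.9, 0.001, 0.001, "unchanged")
        assert r.klass == "unchanged"
        rng = np.random.default_rng(0)
        a = self.counts([9.5] * 20, 300, rng, "a")
        b = self.counts([5.0] * 20, 300, rng, "b")
        res = differential_classes(a, b)
        assert all(x.klass == "unchanged" for x in res if x.fold_change < 2.0)

    def test_label_permutation_level_control(self, rng):
        means = rng.uniform(2, 8, 100)
        pooled = self.counts(means, 80, rng, "c")
        sig_fractions = []
        for _ in range(10):
            perm = rng.permutation(80)
            a = pooled.iloc[:, perm[:40]]
            b = pooled.iloc[:, perm[40:]]
            res = differential_classes(a, b)
            sig_fractions.append(np.mean([r.q_value <= 0.05 for r in res]))
        assert np.mean(sig_fractions) <= 0.05

    def test_too_few_cells_errors(self, rng):
        a = self.counts([5], 1, rng, "a")
        with pytest.raises(ValueError):
            differential_classes(a, a.copy())
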