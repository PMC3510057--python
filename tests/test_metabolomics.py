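import numpy as np
import pandas as pd
import pytest

from pkdnet import metabolomics as metab
from pkdnet import simulate as sim
from pkdnet.datatypes import CompoundRecord, PeakTable


ACETYLCARNITINE_M = sim.formula_mass("C9H17NO4")


def _peak_table(rows, intensities, sample_ids):
    feats = pd.DataFrame(rows).set_index("feature_id")
    inten = pd.DataFrame(
        np.asarray(intensities, float), index=feats.index, columns=sample_ids
    )
    return PeakTable(feats, inten)


class TestFilterFeatures:
    def _meta(self, two_group_meta):
        return two_group_meta(6, 6, prefix="u")

    def test_mean_floor_excludes(self, two_group_meta):
        meta = self._meta(two_group_meta)
        pt = _peak_table(
            [{"feature_id": "f1", "mode": "positive", "mz": 100.0, "rt": 1.0}],
            [[0.5] * 6 + [0.05] * 6],
            meta.sample_ids,
        )
        kept, stats = metab.filter_features(pt, meta)
        assert not stats.loc["f1", "retained"]

    def test_clear_differential_retained(self, two_group_meta):
        meta = self._meta(two_group_meta)
        rng = np.random.default_rng(0)
        ctrl = 0.4 + rng.normal(0, 0.02, 6)
        mut = 0.9 + rng.normal(0, 0.02, 6)
        noise = [0.5 + rng.normal(0, 0.05, 12) for _ in range(30)]
        rows = [
            {"feature_id": f"f{i}", "mode": "positive", "mz": 100.0 + i, "rt": 1.0}
            for i in range(31)
        ]
        pt = _peak_table(rows, [np.concatenate([ctrl, mut])] + noise, meta.sample_ids)
        kept, stats = metab.filter_features(pt, meta)
        assert stats.loc["f0", "retained"]
        assert stats.loc["f0", "fold_change"] > 2

    def test_planted_vs_null_retention(self):
        hits, null_rate = 0, []
        n = 20
        for seed in range(n):
            db = sim.gen_compound_db(3, seed=seed)
            pt, meta, truth = sim.gen_peak_table(
                db,
                {"acetylcarnitine": ("+H", "positive", 4.0)},
                n_noise_features=500,
                seed=seed,
            )
            kept, stats = metab.filter_features(pt, meta)
            hits += "F0000" in kept.feature_ids
            null_rate.append(
                (stats["retained"] & (stats.index != "F0000")).mean()
            )
        assert hits / n >= 0.95
        assert np.mean(null_rate) <= 0.02

    def test_missing_group_errors(self, two_group_meta):
        meta = two_group_meta(12, 0, prefix="u")
        pt = _peak_table(
            [{"feature_id": "f1", "mode": "positive", "mz": 100.0, "rt": 1.0}],
            [[1.0] * 12],
            meta.sample_ids,
        )
        with pytest.raises(ValueError, match="per genotype"):
            metab.filter_features(pt, meta)


class TestAnnotateMz:
    def _single_feature(self, mz, mode="positive"):
        return _peak_table(
            [{"feature_id": "f1", "mode": mode, "mz": mz, "rt": 1.0}],
            [[1.0, 1.0]],
            ["s1", "s2"],
        )

    def test_acetylcarnitine_protonated_match(self):
        db = [CompoundRecord("acetylcarnitine", "C9H17NO4", ACETYLCARNITINE_M)]
        ann = metab.annotate_mz(self._single_feature(204.1230), db)
        assert len(ann) == 1
        assert ann.loc[0, "compound_id"] == "acetylcarnitine"
        assert ann.loc[0, "adduct"] == "+H"
        assert abs(ann.loc[0, "ppm_error"]) < 1.0
        # the theoretical protonated mass itself prints as 204.123
        assert ann.loc[0, "theoretical_mz"] == pytest.approx(204.123, abs=5e-4)

    def test_tolerance_degenerate(self):
        db = [CompoundRecord("acetylcarnitine", "C9H17NO4", ACETYLCARNITINE_M)]
        off = 204.1230 * (1 + 3e-6)  # 3 ppm away
        ann = metab.annotate_mz(self._single_feature(off), db, tol_ppm=0.1)
        assert len(ann) == 0

    def test_mode_restricts_rules(self):
        db = [CompoundRecord("acetylcarnitine", "C9H17NO4", ACETYLCARNITINE_M)]
        ann = metab.annotate_mz(self._single_feature(204.1230, mode="negative"), db)
        assert len(ann) == 0  # +H only applies in positive mode

    def test_db_order_invariant(self):
        rng = np.random.default_rng(0)
        db = sim.gen_compound_db(20, seed=0)
        pt, _, _ = sim.gen_peak_table(
            db,
            {r.compound_id: ("+H", "positive", 2.0) for r in db[:5]},
            n_noise_features=10,
            seed=0,
        )
        a1 = metab.annotate_mz(pt, db)
        shuffled = list(db)
        rng.shuffle(shuffled)
        a2 = metab.annotate_mz(pt, shuffled)
        key = lambda t: sorted(zip(t["feature_id"], t["compound_id"], t["adduct"]))
        assert key(a1) == key(a2)

    def test_planted_recovery_precision_recall(self):
        precs, recs = [], []
        for seed in range(10):
            db = sim.gen_compound_db(30, seed=seed)
            planted = {r.compound_id: ("+H", "positive", 3.0) for r in db[:10]}
            pt, _, truth = sim.gen_peak_table(
                db, planted, n_noise_features=50, ppm_jitter_sd=1.0, seed=seed
            )
            ann = metab.annotate_mz(pt, db)
            truth_pairs = {
                (f, r.truth_compound, r.truth_adduct)
                for f, r in truth.iterrows()
                if r.truth_compound
            }
            got = {
                (r.feature_id, r.compound_id, r.adduct) for r in ann.itertuples()
            }
            tp = len(got & truth_pairs)
            precs.append(tp / len(got))
            recs.append(tp / len(truth_pairs))
        assert np.mean(precs) >= 0.95
        assert np.mean(recs) >= 0.95

    def test_empty_db_errors(self):
        with pytest.raises(ValueError, match="empty"):
            metab.annotate_mz(self._single_feature(100.0), [])


class TestCompoundEnrichment:
    def test_contained_pathway_ordering_and_disjoint(self):
        universe = [f"c{i}" for i in range(40)]
        pathways = {
            "contained": set(universe[:5]),
            "half": set(universe[3:13]),
            "disjoint": set(universe[30:35]),
        }
        annotated = set(universe[:8])
        tab = metab.compound_enrichment(annotated, pathways, universe)
        assert tab.index[0] == "contained"
        assert tab.loc["disjoint", "p"] == pytest.approx(1.0)
        assert tab.loc["contained", "ratio"] == "5/5"

    def test_planted_enrichment_flagged(self):
        rng = np.random.default_rng(0)
        hits = 0
        n = 20
        for seed in range(n):
            rng = np.random.default_rng(seed)
            universe = [f"c{i}" for i in range(200)]
            pathway = set(universe[:10])
            background = [c for c in universe if c not in pathway]
            annotated = set(rng.choice(sorted(pathway), 8, replace=False)) | set(
                rng.choice(background, int(0.05 * len(background)), replace=False)
            )
            pathways = {"target": pathway}
            for i in range(9):
                pathways[f"decoy{i}"] = set(
                    rng.choice(background, 10, replace=False)
                )
            tab = metab.compound_enrichment(annotated, pathways, universe)
            hits += tab.loc["target", "q"] < 0.05
        assert hits / n >= 0.95

    def test_pathway_outside_universe_errors(self):
        with pytest.raises(ValueError, match="outside"):
            metab.compound_enrichment({"a"}, {"p": {"zzz"}}, {"a", "b"})


class TestPlsVip:
    def test_vip_square_mean_is_one(self):
        db = sim.gen_compound_db(30, seed=0)
        pt, meta, _ = sim.gen_peak_table(
            db, {"acetylcarnitine": ("+H", "positive", 4.0)}, seed=0
        )
        vip = metab.pls_vip(pt, meta)
        assert (vip["vip"] ** 2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_perfect_predictor_ranks_first(self, two_group_meta):
        meta = two_group_meta(8, 8, prefix="u")
        rng = np.random.default_rng(0)
        y = np.array([0.0] * 8 + [1.0] * 8)
        rows = [
            {"feature_id": f"f{i}", "mode": "positive", "mz": 100.0 + i, "rt": 1.0}
            for i in range(20)
        ]
        inten = [y * 2 + 1.0] + [
            1.0 + 0.3 * np.abs(rng.standard_normal(16)) for _ in range(19)
        ]
        pt = _peak_table(rows, inten, meta.sample_ids)
        vip = metab.pls_vip(pt, meta, n_components=2)
        assert vip.index[0] == "f0"

    def test_scale_invariant(self):
        db = sim.gen_compound_db(10, seed=1)
        pt, meta, _ = sim.gen_peak_table(
            db, {"acetylcarnitine": ("+H", "positive", 4.0)}, seed=1
        )
        vip1 = metab.pls_vip(pt, meta)
        scaled = PeakTable(pt.features, pt.intensities * 1000.0)
        vip2 = metab.pls_vip(scaled, meta)
        assert np.allclose(vip1["vip"], vip2["vip"], atol=1e-8)

    def test_excess_components_error(self, two_group_meta):
        meta = two_group_meta(3, 3, prefix="u")
        rows = [
            {"feature_id": "f0", "mode": "positive", "mz": 100.0, "rt": 1.0},
            {"feature_id": "f1", "mode": "positive", "mz": 101.0, "rt": 1.0},
        ]
        pt = _peak_table(rows, np.ones((2, 6)) + np.eye(2, 6), meta.sample_ids)
        with pytest.raises(ValueError, match="n_components"):
            metab.pls_vip(pt, meta, n_components=5)
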