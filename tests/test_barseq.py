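"""BarSeq counting, the growth-rate equation chain, and sd shrinkage."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dmskit.barseq import (
    BarcodeLibrary,
    BarSeqCounts,
    BarSeqModel,
    CloneRecord,
    aggregate_single_mutants,
    count_barcodes,
    fit_sd_prior,
    regularize_sd,
)
from dmskit.seqcore import CodonVariant


# ---------------------------------------------------------------------------
# barcode counting
# ---------------------------------------------------------------------------

BC_A = "A" * 25
BC_C = "C" * 25
# two barcodes at Hamming distance 2 from each other: the midpoint read
# is distance 1 from both and therefore ambiguous
BC_X = "G" * 23 + "AA"
BC_Y = "G" * 23 + "CC"
BC_MID = "G" * 23 + "AC"

TAGS = {"TT": (0.0, "permissive", 1), "GG": (6.0, "selective", 1)}
POOLS = {(0.0, "permissive", 1): 1e6, (6.0, "selective", 1): 2e6}


@pytest.fixture
def library():
    return BarcodeLibrary(
        {
            BC_A: CloneRecord("c1", (CodonVariant(2, "AAA", "GAA"),)),
            BC_C: CloneRecord("c2", (), "null_control"),
            BC_X: CloneRecord("c3", (), "wt_control"),
            BC_Y: CloneRecord("c4", (), "wt_control"),
        }
    )


class TestCountBarcodes:
    def test_exact_reads_all_assigned(self, library):
        reads = ["TT" + BC_A] * 60 + ["GG" + BC_C] * 40
        counts, unmatched = count_barcodes(reads, library, TAGS, POOLS)
        assert counts.counts.to_numpy().sum() == 100
        assert unmatched == 0
        assert counts.counts.loc["c1", (0.0, "permissive", 1)] == 60

    def test_one_mismatch_rescue(self, library):
        mutated = "T" + BC_A[1:]
        counts, unmatched = count_barcodes(["TT" + mutated], library, TAGS, POOLS)
        assert unmatched == 0
        assert counts.counts.loc["c1", (0.0, "permissive", 1)] == 1

    def test_ambiguous_neighbor_unmatched(self, library):
        counts, unmatched = count_barcodes(["TT" + BC_MID], library, TAGS, POOLS)
        assert unmatched == 1
        assert counts.counts.to_numpy().sum() == 0

    def test_unknown_tag_unmatched(self, library):
        _, unmatched = count_barcodes(["CC" + BC_A], library, TAGS, POOLS)
        assert unmatched == 1

    def test_unequal_tag_lengths_rejected(self, library):
        tags = {"TT": (0.0, "permissive", 1), "GGG": (6.0, "selective", 1)}
        with pytest.raises(ValueError):
            count_barcodes([], library, tags, POOLS)


# ---------------------------------------------------------------------------
# sd regularization
# ---------------------------------------------------------------------------

class TestRegularizeSd:
    def test_worked_examples(self):
        assert regularize_sd(0.2, 3, 0.3, v0=3) == pytest.approx(
            np.sqrt((3 * 0.09 + 2 * 0.04) / 4), rel=1e-12
        )
        assert regularize_sd(0.3, 3, 0.3, v0=3) == pytest.approx(
            np.sqrt(5 * 0.09 / 4), rel=1e-12
        )

    def test_monotone_in_empirical_sd(self):
        sds = [regularize_sd(s, 3, 0.3, v0=3) for s in (0.1, 0.2, 0.4, 0.8)]
        assert sds == sorted(sds)
        assert len(set(sds)) == 4

    def test_degenerate_denominator(self):
        with pytest.raises(ValueError):
            regularize_sd(0.2, 2, 0.3, v0=0)
        with pytest.raises(ValueError):
            regularize_sd(0.2, 1, 0.3)


class TestSdPrior:
    def test_exact_linear_data_recovered(self):
        rng = np.random.default_rng(0)
        counts = 10 ** rng.uniform(1, 4, size=40)
        s = rng.uniform(0, 1, size=40)
        sd = 0.3 - 0.05 * np.log10(counts) + 0.1 * s
        pred = fit_sd_prior(sd, counts, s)
        assert np.allclose(pred, sd, atol=1e-10)

    def test_negative_count_coefficient_ordering(self):
        rng = np.random.default_rng(1)
        counts = 10 ** rng.uniform(1, 4, size=60)
        s = rng.uniform(0, 1, size=60)
        sd = 0.4 - 0.08 * np.log10(counts) + 0.01 * s + rng.normal(0, 0.005, 60)
        # NaN sd: excluded from the fit but still predicted
        sd_ext = np.append(sd, np.nan)
        pred_high = fit_sd_prior(sd_ext, np.append(counts, 1e6), np.append(s, 1.0))[-1]
        pred_low = fit_sd_prior(sd_ext, np.append(counts, 10.0), np.append(s, 1.0))[-1]
        assert pred_high <= pred_low

    def test_floor_applies(self):
        rng = np.random.default_rng(2)
        counts = np.full(20, 1e3)
        s = rng.uniform(0, 1, 20)
        sd = np.full(20, 1e-6)
        assert (fit_sd_prior(sd, counts, s, floor=0.01) >= 0.01).all()

    def test_too_few_clones(self):
        with pytest.raises(ValueError):
            fit_sd_prior(np.ones(5), np.ones(5), np.ones(5))


# ---------------------------------------------------------------------------
# the equation chain on micro-instances (independent oracle)
# ---------------------------------------------------------------------------

def _oracle_chain(counts, pools, timepoints, reps, null_ids, wt_ids, pseudo=0.0):
    """Plain-dict reimplementation of the scoring chain.

    counts[(clone, t, tau, rep)] -> count; pools[(t, tau, rep)] -> P*.
    Returns the final (re-anchored) mean score per clone.
    """
    clones = sorted({k[0] for k in counts})
    s_prime = {}
    for rep in reps:
        s = {}
        for clone in clones:
            prod = 1.0
            for k in range(1, len(timepoints)):
                t1, t0 = timepoints[k], timepoints[k - 1]
                dt = t1 - t0
                phis = {}
                for tau in ("permissive", "selective"):
                    tot1 = sum(counts[(c, t1, tau, rep)] + pseudo for c in clones)
                    tot0 = sum(counts[(c, t0, tau, rep)] + pseudo for c in clones)
                    r1 = (counts[(clone, t1, tau, rep)] + pseudo) / tot1
                    r0 = (counts[(clone, t0, tau, rep)] + pseudo) / tot0
                    P1, P0 = r1 * pools[(t1, tau, rep)], r0 * pools[(t0, tau, rep)]
                    rho = (P1 / P0) ** (1.0 / dt)
                    rho_star = (
                        pools[(t1, tau, rep)] / pools[(t0, tau, rep)]
                    ) ** (1.0 / dt)
                    phis[tau] = rho / rho_star
                prod *= phis["selective"] / phis["permissive"]
            s[clone] = prod
        s_null = float(np.median([s[c] for c in null_ids]))
        s_wt = float(np.median([s[c] for c in wt_ids]))
        for clone in clones:
            s_prime.setdefault(clone, []).append(
                (s[clone] - s_null) / (s_wt - s_null)
            )
    mean = {c: float(np.mean(v)) for c, v in s_prime.items()}
    null_med = float(np.median([mean[c] for c in null_ids]))
    wt_med = float(np.median([mean[c] for c in wt_ids]))
    return {c: (mean[c] - null_med) / (wt_med - null_med) for c in clones}


def _build_counts(raw, pools):
    clones = sorted({k[0] for k in raw})
    samples = sorted({k[1:] for k in raw})
    mat = pd.DataFrame(
        {s: [raw[(c, *s)] for c in clones] for s in samples},
        index=pd.Index(clones, name="clone_id"),
    )
    mat.columns = pd.MultiIndex.from_tuples(
        mat.columns, names=["timepoint_h", "temperature", "replicate"]
    )
    psize = pd.Series(pools)
    psize.index = pd.MultiIndex.from_tuples(
        psize.index, names=["timepoint_h", "temperature", "replicate"]
    )
    return BarSeqCounts(mat, psize)


def _micro_instance(n_reps=1, seed=0):
    rng = np.random.default_rng(seed)
    clones = ["v1", "n1", "w1", "w2"]
    raw, pools = {}, {}
    for rep in range(1, n_reps + 1):
        for t in (0.0, 12.0):
            for tau in ("permissive", "selective"):
                pools[(t, tau, rep)] = float(rng.integers(10**6, 10**7))
                for c in clones:
                    raw[(c, t, tau, rep)] = int(rng.integers(50, 5000))
    library = BarcodeLibrary(
        {
            "A" * 25: CloneRecord("v1", (CodonVariant(2, "AAA", "GAA"),)),
            "C" * 25: CloneRecord("n1", (), "null_control"),
            "G" * 25: CloneRecord("w1", (), "wt_control"),
            "T" * 25: CloneRecord("w2", (), "wt_control"),
        }
    )
    return raw, pools, library


class TestFitnessChain:
    @pytest.mark.parametrize("n_reps, seed", [(1, 0), (3, 1), (3, 2)])
    def test_matches_independent_arithmetic(self, n_reps, seed):
        raw, pools, library = _micro_instance(n_reps, seed)
        counts = _build_counts(raw, pools)
        res = BarSeqModel(counts, library, pseudocount=0.0).fit()
        expected = _oracle_chain(
            raw, pools, [0.0, 12.0], range(1, n_reps + 1), ["n1"], ["w1", "w2"]
        )
        for clone, value in expected.items():
            assert res.clone_scores.loc[clone, "s_prime"] == pytest.approx(
                value, rel=1e-12
            )

    def test_control_tracking_clones_anchor(self):
        # a clone whose counts exactly track wt controls scores exactly 1
        raw, pools, library = _micro_instance(3, seed=3)
        for key in list(raw):
            if key[0] in ("v1", "w2"):
                raw[key] = raw[("w1", *key[1:])]
        counts = _build_counts(raw, pools)
        res = BarSeqModel(counts, library, pseudocount=0.0).fit()
        assert res.clone_scores.loc["v1", "s_prime"] == pytest.approx(1.0, abs=1e-12)
        # and one tracking the null control scores exactly 0
        for key in list(raw):
            if key[0] == "v1":
                raw[key] = raw[("n1", *key[1:])]
        res = BarSeqModel(_build_counts(raw, pools), library, pseudocount=0.0).fit()
        assert res.clone_scores.loc["v1", "s_prime"] == pytest.approx(0.0, abs=1e-12)

    def test_depth_invariance(self):
        """Scaling all counts in one sample leaves every score unchanged."""
        raw, pools, library = _micro_instance(3, seed=4)
        base = BarSeqModel(
            _build_counts(raw, pools), library, pseudocount=0.0
        ).fit()
        scaled = {
            k: (v * 17 if k[1:] == (12.0, "selective", 2) else v)
            for k, v in raw.items()
        }
        res = BarSeqModel(
            _build_counts(scaled, pools), library, pseudocount=0.0
        ).fit()
        pd.testing.assert_series_equal(
            base.clone_scores["s_prime"], res.clone_scores["s_prime"]
        )

    def test_missing_controls_rejected(self):
        raw, pools, _ = _micro_instance()
        library = BarcodeLibrary(
            {
                "A" * 25: CloneRecord("v1", ()),
                "C" * 25: CloneRecord("n1", ()),
                "G" * 25: CloneRecord("w1", ()),
                "T" * 25: CloneRecord("w2", ()),
            }
        )
        with pytest.raises(ValueError, match="control"):
            BarSeqModel(_build_counts(raw, pools), library)


# ---------------------------------------------------------------------------
# aggregation across biological replicates
# ---------------------------------------------------------------------------

def _scores_frame(records):
    df = pd.DataFrame(records).set_index("clone_id")
    df["sd_reg"] = df["se"]
    df["df"] = 3
    return df


class TestAggregateSingleMutants:
    @pytest.fixture
    def lib(self):
        v = (CodonVariant(2, "AAA", "GAA"),)
        return BarcodeLibrary(
            {
                "A" * 25: CloneRecord("a", v),
                "C" * 25: CloneRecord("b", v),
                "G" * 25: CloneRecord("n", (), "null_control"),
                "T" * 25: CloneRecord("w", (), "wt_control"),
            }
        )

    def test_equal_weights_average(self, lib):
        scores = _scores_frame(
            [
                {"clone_id": "a", "s_prime": 0.4, "se": 0.1},
                {"clone_id": "b", "s_prime": 0.6, "se": 0.1},
            ]
        )
        out = aggregate_single_mutants(scores, lib)
        assert len(out) == 1
        assert out.score.iloc[0] == pytest.approx(0.5)
        assert out.n_clones.iloc[0] == 2

    def test_inverse_variance_weights(self, lib):
        scores = _scores_frame(
            [
                {"clone_id": "a", "s_prime": 0.2, "se": 0.1},
                {"clone_id": "b", "s_prime": 0.8, "se": 0.4},
            ]
        )
        out = aggregate_single_mutants(scores, lib)
        expected = (0.2 / 0.01 + 0.8 / 0.16) / (1 / 0.01 + 1 / 0.16)
        assert out.score.iloc[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(25.0 / 106.25)

    def test_single_clone_passthrough(self, lib):
        scores = _scores_frame([{"clone_id": "a", "s_prime": 0.37, "se": 0.05}])
        out = aggregate_single_mutants(scores, lib)
        assert out.score.iloc[0] == pytest.approx(0.37)
        assert out.se.iloc[0] == pytest.approx(0.05)

    def test_multi_mutant_clones_excluded(self):
        lib = BarcodeLibrary(
            {
                "A" * 25: CloneRecord(
                    "m", (CodonVariant(2, "AAA", "GAA"), CodonVariant(3, "GAA", "TGG"))
                ),
                "G" * 25: CloneRecord("n", (), "null_control"),
                "T" * 25: CloneRecord("w", (), "wt_control"),
            }
        )
        scores = _scores_frame([{"clone_id": "m", "s_prime": 0.4, "se": 0.1}])
        assert aggregate_single_mutants(scores, lib).empty

    def test_synonymous_codon_changes_ignored(self):
        # one missense + one synonymous change is still a single mutant
        lib = BarcodeLibrary(
            {
                "A" * 25: CloneRecord(
                    "m", (CodonVariant(2, "AAA", "GAA"), CodonVariant(3, "GAA", "GAG"))
                ),
                "G" * 25: CloneRecord("n", (), "null_control"),
                "T" * 25: CloneRecord("w", (), "wt_control"),
            }
        )
        scores = _scores_frame([{"clone_id": "m", "s_prime": 0.4, "se": 0.1}])
        out = aggregate_single_mutants(scores, lib)
        assert len(out) == 1 and out.position.iloc[0] == 2


# ---------------------------------------------------------------------------
# end-to-end on the simulator
# ---------------------------------------------------------------------------

class TestSimulatedRecovery:
    def test_control_medians_exact_and_truth_recovered(self, barseq_sim):
        cfg, orf, pool, truth, library, counts = barseq_sim
        res = BarSeqModel(counts, library).fit()
        cs = res.clone_scores
        assert cs.loc[cs.control_class == "null_control", "s_prime"].median() == 0.0
        assert cs.loc[cs.control_class == "wt_control", "s_prime"].median() == 1.0
        sp = cs["s_prime"].reindex(pool.clone_id)
        r = np.corrcoef(sp, pool.fitness)[0, 1]
        assert r >= 0.9

    def test_variant_aggregation_produces_map(self, barseq_sim):
        cfg, orf, pool, truth, library, counts = barseq_sim
        res = BarSeqModel(counts, library).fit()
        vs = res.variant_scores("SYN")
        assert (vs.n_clones >= 1).all()
        assert set(vs.provenance) == {"measured"}
        assert vs.se.gt(0).all()
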