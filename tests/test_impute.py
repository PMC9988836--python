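"""Viterbi HMM imputation: panel selection, decoding and panel imputation."""

import itertools

import numpy as np
import pytest

from conftest import make_matrix
from modmap.datatypes import MISSING, GenotypeMatrix
from modmap.impute import (
    HmmParams,
    impute_panel,
    impute_strain,
    select_reference_panel,
    viterbi_decode,
)
from modmap.simulate import PanelSimConfig, simulate_strain_panel


def brute_force_viterbi(target, panel, params):
    """Exhaustive maximization over all k^m state paths."""
    m, k = panel.shape
    log_stay = np.log1p(-params.tau)
    log_switch = np.log(params.tau / (k - 1)) if k > 1 else 0.0
    best, best_path = -np.inf, None
    for path in itertools.product(range(k), repeat=m):
        s = -np.log(k)
        for t in range(m):
            if t > 0:
                s += log_stay if path[t] == path[t - 1] else log_switch
            tc, pc = target[t], panel[t, path[t]]
            if tc != MISSING and pc != MISSING:
                s += np.log1p(-params.epsilon) if tc == pc else np.log(params.epsilon)
        if s > best + 1e-12:
            best, best_path = s, path
    return best, np.array(best_path)


class TestPanelSelection:
    def test_identical_candidate_first(self):
        calls = np.array([[0, 0, 1], [1, 1, 0], [0, 0, 1], [1, 1, 1]])
        gm = make_matrix(calls, strains=["T", "Twin", "Other"])
        panel = select_reference_panel(gm, "T", 2)
        assert panel[0] == "Twin"

    def test_k_exceeds_candidates_warns(self, tiny_matrix):
        gm = make_matrix(np.zeros((3, 3), dtype=int))
        with pytest.warns(UserWarning, match="only 2 candidate"):
            panel = select_reference_panel(gm, "S1", 5)
        assert len(panel) == 2

    def test_matches_brute_force_concordance(self, rng):
        for _ in range(5):
            calls = rng.choice([0, 1, MISSING], size=(40, 8), p=[0.4, 0.4, 0.2])
            calls[:2] = 0  # guarantee overlap
            gm = make_matrix(calls)
            ranked = select_reference_panel(gm, "S1", 7)
            conc = {}
            for j in range(1, 8):
                both = (calls[:, 0] != MISSING) & (calls[:, j] != MISSING)
                conc[f"S{j + 1}"] = (calls[both, 0] == calls[both, j]).mean()
            expect = sorted(conc, key=lambda s: (-conc[s], s))
            assert ranked == expect


class TestViterbi:
    def test_perfect_match_constant_path(self):
        panel = np.array([[0, 1], [1, 0], [0, 1], [1, 1]], dtype=np.int8)
        target = panel[:, 1].copy()
        path = viterbi_decode(target, panel, HmmParams(epsilon=1e-4, tau=0.01, k=2))
        assert (path.states == 1).all()

    def test_matches_brute_force(self, rng):
        params_pool = [
            HmmParams(epsilon=e, tau=t, k=4)
            for e in (0.01, 0.2)
            for t in (0.002, 0.3)
        ]
        for trial in range(60):
            k = int(rng.integers(2, 5))
            m = int(rng.integers(2, 9))
            panel = rng.choice([0, 1, MISSING], size=(m, k)).astype(np.int8)
            target = rng.choice([0, 1, MISSING], size=m).astype(np.int8)
            if (target == MISSING).all():
                target[0] = 0
            params = params_pool[trial % len(params_pool)]
            vp = viterbi_decode(target, panel[:, :k], params)
            bs, bp = brute_force_viterbi(target, panel[:, :k], params)
            assert vp.log_score == pytest.approx(bs, abs=1e-9)

    def test_single_switch_located(self):
        """Target tracks reference A for SNPs 1-10 then B for 11-20: exactly
        one switch, between SNPs 10 and 11."""
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, size=20).astype(np.int8)
        b = 1 - a
        panel = np.column_stack([a, b])
        target = np.r_[a[:10], b[10:]].astype(np.int8)
        path = viterbi_decode(target, panel, HmmParams(epsilon=0.01, tau=0.01, k=2))
        assert (path.states[:10] == 0).all() and (path.states[10:] == 1).all()

    def test_score_beats_random_paths(self, rng):
        m, k = 30, 4
        panel = rng.integers(0, 2, size=(m, k)).astype(np.int8)
        target = rng.integers(0, 2, size=m).astype(np.int8)
        params = HmmParams(epsilon=0.05, tau=0.01, k=k)
        vp = viterbi_decode(target, panel, params)
        log_stay, log_switch = np.log1p(-params.tau), np.log(params.tau / (k - 1))
        for _ in range(1000):
            path = rng.integers(0, k, size=m)
            s = -np.log(k)
            for t in range(m):
                if t > 0:
                    s += log_stay if path[t] == path[t - 1] else log_switch
                s += np.log1p(-params.epsilon) if target[t] == panel[t, path[t]] else np.log(
                    params.epsilon
                )
            assert vp.log_score >= s - 1e-9

    def test_determinism(self, rng):
        panel = rng.integers(0, 2, size=(25, 3)).astype(np.int8)
        target = rng.integers(0, 2, size=25).astype(np.int8)
        params = HmmParams()
        p1 = viterbi_decode(target, panel, params)
        p2 = viterbi_decode(target, panel, params)
        assert np.array_equal(p1.states, p2.states)


class TestImpute:
    def test_no_missing_identity(self, rng):
        calls = rng.integers(0, 2, size=(30, 5)).astype(np.int8)
        gm = make_matrix(calls)
        out, summary = impute_panel(gm)
        assert out == gm
        assert summary.attrs["median_post_missing"] == 0.0

    def test_observed_calls_never_altered(self, rng):
        calls = rng.choice([0, 1, MISSING], size=(50, 6), p=[0.4, 0.4, 0.2]).astype(np.int8)
        calls[:3] = 0
        gm = make_matrix(calls)
        out, _ = impute_panel(gm)
        observed = calls != MISSING
        assert np.array_equal(out.calls[observed], calls[observed])

    def test_reference_missing_stays_missing(self):
        # both strains missing at SNP 1: nothing can fill it
        calls = np.array([[0, 0], [MISSING, MISSING], [1, 1]], dtype=np.int8)
        gm = make_matrix(calls)
        imputed, report = impute_strain(gm, "S1", HmmParams(k=1))
        assert imputed[1] == MISSING
        assert report["post_missing"] > 0

    def test_residual_missingness_monotone(self, rng):
        for s in range(3):
            r = np.random.default_rng(s)
            calls = r.choice([0, 1, MISSING], size=(60, 8), p=[0.35, 0.35, 0.3]).astype(np.int8)
            calls[:2] = 0
            gm = make_matrix(calls)
            out, summary = impute_panel(gm)
            assert (summary["post_missing"] <= summary["pre_missing"] + 1e-12).all()

    def test_masking_recovery_low_divergence(self):
        """>=95% of calls masked in target strains are recovered on a
        low-divergence group-structured panel."""
        accs = []
        for s in range(6):
            gm = simulate_strain_panel(
                PanelSimConfig(
                    n_groups=4, strains_per_group=5, n_snps=500,
                    within_group_diversity=0.01, missing_rate_range=(0, 0), seed=700 + s,
                )
            )
            truth = gm.calls.copy()
            r = np.random.default_rng(800 + s)
            mask = np.zeros_like(truth, dtype=bool)
            mask[:, [0, 5, 10, 15]] = r.random((500, 4)) < 0.2
            masked = truth.copy()
            masked[mask] = MISSING
            out, _ = impute_panel(GenotypeMatrix(gm.variants, gm.strains, masked))
            accs.append(((out.calls == truth) & mask).sum() / mask.sum())
        assert np.mean(accs) >= 0.95
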