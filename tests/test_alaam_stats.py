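"""Configuration statistics and change statistics."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_multilevel_net
from wealthnet.alaam_stats import (
    AlaamModel,
    Effect,
    EffectSpec,
    OutcomeState,
    full_effect_spec,
)
from wealthnet.network_build import MultilevelNetwork, TieInfo, affiliate


def naive_statistics(model, state, cov=None, rcov=None):
    """Independent loop-based recount of every implemented statistic."""
    net = model.net
    y = {h: int(state.y[i]) for i, h in enumerate(model.h_ids)}
    Y = {r: int(state.Y[i]) for i, r in enumerate(model.r_ids)}
    aff = net.affiliation
    edges = list(net.ties)
    deg = {h: 0 for h in model.h_ids}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    eset = {frozenset(e) for e in edges}
    # triangles per node: adjacent neighbour pairs
    tri = {h: 0 for h in model.h_ids}
    nbrs = {h: set() for h in model.h_ids}
    for a, b in edges:
        nbrs[a].add(b)
        nbrs[b].add(a)
    for h in model.h_ids:
        ns = sorted(nbrs[h], key=str)
        for i in range(len(ns)):
            for j in range(i + 1, len(ns)):
                if frozenset((ns[i], ns[j])) in eset:
                    tri[h] += 1
    out = []
    for e in model.spec:
        k = e.kind
        if k == "density_household":
            v = sum(y.values())
        elif k == "activity_household":
            v = sum(y[h] * deg[h] for h in model.h_ids)
        elif k == "closure_household":
            v = sum(y[h] * tri[h] for h in model.h_ids)
        elif k == "degree_same_region":
            v = sum(y[h] * sum(1 for n in nbrs[h] if aff[n] == aff[h]) for h in model.h_ids)
        elif k == "degree_cross_region":
            v = sum(y[h] * sum(1 for n in nbrs[h] if aff[n] != aff[h]) for h in model.h_ids)
        elif k == "household_covariate":
            v = sum(y[h] * cov.loc[h, e.covariate] for h in model.h_ids)
        elif k == "contagion_same_region":
            v = sum(y[a] * y[b] for a, b in edges if aff[a] == aff[b])
        elif k == "contagion_cross_region":
            v = sum(y[a] * y[b] for a, b in edges if aff[a] != aff[b])
        elif k == "contagion_poorest":
            q = cov["baseline_quintile"]
            v = sum(y[a] * y[b] for a, b in edges if q[a] == 1 and q[b] == 1)
        elif k == "density_region":
            v = sum(Y.values())
        elif k == "within_region_ties":
            v = sum(
                Y[r] * sum(1 for a, b in edges if aff[a] == r and aff[b] == r)
                for r in model.r_ids
            )
        elif k == "cross_region_ties":
            v = sum(
                Y[r]
                * sum(1 for a, b in edges if (aff[a] == r) != (aff[b] == r))
                for r in model.r_ids
            )
        elif k == "region_covariate":
            v = sum(Y[r] * rcov.loc[r, e.covariate] for r in model.r_ids)
        elif k == "contagion_region":
            v = sum(Y[a] * Y[b] for a, b in net.meta_ties)
        elif k == "cross_level_interaction":
            v = sum(Y[aff[h]] * y[h] for h in model.h_ids)
        elif k == "micro_macro_link":
            v = sum(
                Y[r] * sum(y[a] * y[b] for a, b in edges if aff[a] == r and aff[b] == r)
                for r in model.r_ids
            )
        else:
            raise AssertionError(k)
        out.append(float(v))
    return np.array(out)


@pytest.fixture(scope="module")
def fixture_model():
    net = random_multilevel_net(n_h=30, n_r=3, p=0.09, seed=4)
    rng = np.random.default_rng(9)
    cov = pd.DataFrame(
        {
            "baseline_quintile": rng.integers(1, 6, 30),
            "n_nonresidents": rng.integers(0, 6, 30).astype(float),
        },
        index=pd.Index(range(30)),
    )
    rcov = pd.DataFrame({"inq_w1": rng.random(3)}, index=pd.Index(net.regions))
    spec = full_effect_spec(["n_nonresidents"], ["inq_w1"], include_poorest=True)
    model = AlaamModel(net, spec, covariates=cov, region_covariates=rcov)
    return model, cov, rcov


class TestStatistics:
    def test_zero_state_gives_zero_vector(self, fixture_model):
        model, _, _ = fixture_model
        st = OutcomeState(np.zeros(30, np.int8), np.zeros(3, np.int8))
        assert np.all(model.statistics(st) == 0)

    def test_hand_counted_cross_level_example(self):
        """Two same-region tied households with the outcome, their region too."""
        net = MultilevelNetwork(households=[0, 1, 2], ties={(0, 1): TieInfo(1, 1)})
        net = affiliate(net, {0: 0, 1: 0, 2: 1})
        spec = EffectSpec(
            [
                Effect("density_household"),
                Effect("density_region"),
                Effect("contagion_same_region"),
                Effect("cross_level_interaction"),
                Effect("micro_macro_link"),
            ]
        )
        m = AlaamModel(net, spec)
        st = OutcomeState(np.array([1, 1, 0]), np.array([1, 0]))
        z = dict(zip(spec.names, m.statistics(st)))
        assert z["contagion_same_region"] == 1
        assert z["cross_level_interaction"] == 2
        assert z["micro_macro_link"] == 1

    def test_matches_naive_recount(self, fixture_model):
        model, cov, rcov = fixture_model
        rng = np.random.default_rng(21)
        for _ in range(5):
            st = OutcomeState(
                (rng.random(30) < 0.5).astype(np.int8),
                (rng.random(3) < 0.5).astype(np.int8),
            )
            np.testing.assert_allclose(
                model.statistics(st), naive_statistics(model, st, cov, rcov)
            )

    def test_batch_matches_single(self, fixture_model):
        model, _, _ = fixture_model
        rng = np.random.default_rng(2)
        yb = (rng.random((6, 30)) < 0.5).astype(np.int8)
        Yb = (rng.random((6, 3)) < 0.5).astype(np.int8)
        Z = model.statistics_batch(yb, Yb)
        for i in range(6):
            np.testing.assert_allclose(Z[i], model.statistics(OutcomeState(yb[i], Yb[i])))

    def test_relabelling_invariance(self):
        """Statistics are invariant to household relabelling."""
        net = random_multilevel_net(n_h=15, n_r=2, p=0.2, seed=6)
        spec = full_effect_spec()
        m1 = AlaamModel(net, spec)
        rng = np.random.default_rng(1)
        y = (rng.random(15) < 0.5).astype(np.int8)
        Y = (rng.random(2) < 0.5).astype(np.int8)
        z1 = m1.statistics(OutcomeState(y, Y))

        perm = rng.permutation(15)
        relabel = {h: int(100 + perm[i]) for i, h in enumerate(net.households)}
        ties2 = {
            tuple(sorted((relabel[a], relabel[b]))): info for (a, b), info in net.ties.items()
        }
        net2 = affiliate(
            MultilevelNetwork(households=sorted(relabel.values()), ties=ties2),
            {relabel[h]: net.affiliation[h] for h in net.households},
        )
        m2 = AlaamModel(net2, spec)
        y2 = np.empty(15, np.int8)
        for i, h in enumerate(net.households):
            y2[m2.household_index(relabel[h])] = y[i]
        z2 = m2.statistics(OutcomeState(y2, Y))
        np.testing.assert_allclose(z1, z2)

    def test_missing_covariate_named_in_error(self, fixture_model):
        model, cov, rcov = fixture_model
        spec = EffectSpec(
            [
                Effect("density_household"),
                Effect("density_region"),
                Effect("household_covariate", covariate="no_such_thing"),
            ]
        )
        with pytest.raises(KeyError, match="no_such_thing"):
            AlaamModel(model.net, spec, covariates=cov)


class TestChangeStatistics:
    def test_local_equals_global_difference(self, fixture_model):
        model, _, _ = fixture_model
        rng = np.random.default_rng(8)
        st = OutcomeState(
            (rng.random(30) < 0.5).astype(np.int8), (rng.random(3) < 0.5).astype(np.int8)
        )
        for level, n in (("household", 30), ("region", 3)):
            for i in range(n):
                hi, lo = st.copy(), st.copy()
                (hi.y if level == "household" else hi.Y)[i] = 1
                (lo.y if level == "household" else lo.Y)[i] = 0
                np.testing.assert_allclose(
                    model.change_statistic(st, i, level),
                    model.statistics(hi) - model.statistics(lo),
                    atol=1e-10,
                )

    def test_isolate_density_only(self):
        net = MultilevelNetwork(households=[0, 1], ties={})
        net = affiliate(net, {0: 0, 1: 0})
        m = AlaamModel(net, EffectSpec([Effect("density_household"), Effect("density_region")]))
        st = OutcomeState(np.zeros(2, np.int8), np.zeros(1, np.int8))
        np.testing.assert_allclose(m.change_statistic(st, 0, "household"), [1.0, 0.0])

    def test_same_region_partner_count(self, toy_model):
        st = OutcomeState(np.zeros(12, np.int8), np.zeros(2, np.int8))
        st.y[[1, 2]] = 1  # household 0 has same-region ties to 1 and 2
        dz = toy_model.change_statistic(st, 0, "household")
        assert dz[toy_model.spec.index("contagion_same_region")] == 2

    def test_telescoping_over_flip_sequence(self, fixture_model):
        """Signed change statistics telescope to z(final) - z(initial)."""
        model, _, _ = fixture_model
        rng = np.random.default_rng(12)
        st = OutcomeState(
            (rng.random(30) < 0.5).astype(np.int8), (rng.random(3) < 0.5).astype(np.int8)
        )
        z0 = model.statistics(st)
        total = np.zeros(len(model.spec))
        for _ in range(60):
            if rng.random() < 0.8:
                i, level = int(rng.integers(30)), "household"
                arr = st.y
            else:
                i, level = int(rng.integers(3)), "region"
                arr = st.Y
            new = int(rng.random() < 0.5)
            if new != arr[i]:
                dz = model.change_statistic(st, i, level)
                total += dz if new == 1 else -dz
                arr[i] = new
        np.testing.assert_allclose(z0 + total, model.statistics(st), atol=1e-9)

    def test_masked_node_rejected(self, fixture_model):
        model, _, _ = fixture_model
        st = OutcomeState(
            np.zeros(30, np.int8), np.zeros(3, np.int8), missing_mask=np.eye(1, 30, 5, dtype=bool)[0]
        )
        with pytest.raises(ValueError, match="masked"):
            model.change_statistic(st, 5, "household")


class TestSpecValidation:
    def test_unique_names_required(self):
        with pytest.raises(ValueError, match="unique"):
            EffectSpec([Effect("density_household"), Effect("density_household")])

    def test_covariate_effects_need_name(self):
        with pytest.raises(ValueError, match="covariate"):
            Effect("household_covariate")

    def test_densities_required_for_estimation(self):
        spec = EffectSpec([Effect("contagion_same_region")])
        with pytest.raises(ValueError, match="density"):
            spec.require_densities()

    def test_outcome_entries_validated(self):
        with pytest.raises(ValueError, match="0/1"):
            OutcomeState(np.array([0, 2]), np.array([0]))
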