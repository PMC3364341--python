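"""Protein descriptor families against hand counts and brute-force oracles."""

import numpy as np
import pytest
import yaml

from dtiforge.aadata import ALPHABET, CTD_GROUPS, aaprop_scales, standardize_scale
from dtiforge.exceptions import ConfigError, SequenceError
from dtiforge.proteins import (
    DescriptorProfile,
    PropertyTable,
    ProteinRecord,
    aaprop_features,
    apaac_features,
    autocorrelation_features,
    composition_features,
    ctd_features,
    default_autocorrelation_properties,
    default_distance_matrices,
    featurize_protein,
    order_features,
)

IDX = {r: i for i, r in enumerate(ALPHABET)}


def rec(seq, rid="p"):
    return ProteinRecord(rid, seq)


def random_seq(rng, lo=31, hi=200):
    return "".join(rng.choice(list(ALPHABET), size=int(rng.integers(lo, hi + 1))))


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

class TestComposition:
    def test_homopolymer(self):
        v = composition_features(rec("AAAA"))
        d = dict(zip(v.names, v.values))
        assert d["AAC_A"] == 1.0
        assert sum(v for k, v in d.items() if k.startswith("AAC") and k != "AAC_A") == 0
        assert d["DPC_AA"] == 1.0

    def test_direct_counts(self):
        d = dict(zip(*[(v.names, v.values) for v in [composition_features(rec("ACDA"))]][0]))
        assert d["AAC_A"] == 0.5 and d["AAC_C"] == 0.25 and d["AAC_D"] == 0.25

    def test_dipeptide_hand_count(self):
        v = composition_features(rec("ARAR"))
        d = dict(zip(v.names, v.values))
        assert d["DPC_AR"] == pytest.approx(2 / 3)
        assert d["DPC_RA"] == pytest.approx(1 / 3)

    def test_blocks_sum_to_one(self, rng):
        for _ in range(20):
            v = composition_features(rec(random_seq(rng, lo=2)))
            assert v.values[:20].sum() == pytest.approx(1.0, abs=1e-9)
            assert v.values[20:].sum() == pytest.approx(1.0, abs=1e-9)

    def test_nonstandard_residue_named(self):
        with pytest.raises(SequenceError, match=r"'X' at position 3"):
            composition_features(rec("AAXA"))

    def test_sanitizer_strips(self):
        r = ProteinRecord.from_raw("p", "AAXBA", sanitize=True)
        assert r.sequence == "AAA"


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------

def toy_property(**vals):
    table = {r: 0.0 for r in ALPHABET}
    table.update(vals)
    return PropertyTable("toy", table, standardized=True)


class TestAutocorrelation:
    def test_alternating_moreau_broto(self):
        p = toy_property(A=1.0, R=-1.0)
        v = autocorrelation_features(rec("ARARARARAR"), [p], maxlag=1, kind="moreau_broto")
        assert v.values[0] == pytest.approx(-1.0)

    def test_homopolymer_moran_zero(self):
        props = default_autocorrelation_properties()
        v = autocorrelation_features(rec("A" * 40), props, maxlag=5, kind="moran")
        assert np.all(v.values == 0)

    def test_dimensionality(self):
        p = toy_property(A=1.0, R=-1.0)
        v = autocorrelation_features(rec("AR" * 20), [p], maxlag=30)
        assert len(v) == 30

    def test_too_short_names_minimum(self):
        with pytest.raises(SequenceError, match="length >= 31"):
            autocorrelation_features(rec("A" * 20), [toy_property(A=1.0)], maxlag=30)

    @pytest.mark.parametrize("kind", ["moreau_broto", "moran", "geary"])
    def test_matches_brute_force(self, kind, rng):
        """Direct double-loop evaluation of the defining sums."""
        props = default_autocorrelation_properties()[:3]
        maxlag = 8
        for _ in range(30):
            s = random_seq(rng)
            L = len(s)
            got = autocorrelation_features(rec(s), props, maxlag=maxlag, kind=kind).values
            expected = []
            for prop in props:
                std = standardize_scale(prop.values)
                p = [std[r] for r in s]
                pbar = sum(p) / L
                for d in range(1, maxlag + 1):
                    if kind == "moreau_broto":
                        expected.append(sum(p[i] * p[i + d] for i in range(L - d)) / (L - d))
                    elif kind == "moran":
                        num = sum((p[i] - pbar) * (p[i + d] - pbar) for i in range(L - d)) / (L - d)
                        den = sum((x - pbar) ** 2 for x in p) / L
                        expected.append(num / den if den > 0 else 0.0)
                    else:
                        num = sum((p[i] - p[i + d]) ** 2 for i in range(L - d)) / (2 * (L - d))
                        den = sum((x - pbar) ** 2 for x in p) / (L - 1)
                        expected.append(num / den if den > 0 else 0.0)
            np.testing.assert_allclose(got, expected, atol=1e-9)


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

TOY_GROUPS = {"toy": ("A", "R", "".join(r for r in ALPHABET if r not in "AR"))}


class TestCTD:
    def test_composition_and_transition_hand_count(self):
        v = ctd_features(rec("AAARRR"), groupings=TOY_GROUPS)
        d = dict(zip(v.names, v.values))
        assert d["CTD_C_toy_g1"] == pytest.approx(0.5)
        assert d["CTD_C_toy_g2"] == pytest.approx(0.5)
        assert d["CTD_C_toy_g3"] == 0.0
        assert d["CTD_T_toy_g1g2"] == pytest.approx(1 / 5)

    def test_homogroup_no_transitions(self):
        v = ctd_features(rec("AAAA"), groupings=TOY_GROUPS)
        d = dict(zip(v.names, v.values))
        assert all(d[k] == 0 for k in d if k.startswith("CTD_T"))

    def test_distribution_percentiles(self):
        v = ctd_features(rec("AAARRR"), groupings=TOY_GROUPS)
        d = dict(zip(v.names, v.values))
        got = [d[f"CTD_D_toy_g1_{t}"] for t in ("first", "p25", "p50", "p75", "p100")]
        np.testing.assert_allclose(got, np.array([1, 1, 2, 3, 3]) / 6 * 100)

    def test_default_dimension_and_oracle(self, rng):
        """Composition/transition recomputed by direct counting."""
        for _ in range(20):
            s = random_seq(rng)
            v = ctd_features(rec(s))
            assert len(v) == 147
            d = dict(zip(v.names, v.values))
            for attr, groups in CTD_GROUPS.items():
                gi = {r: g for g, mem in enumerate(groups) for r in mem}
                labs = [gi[r] for r in s]
                for g in range(3):
                    assert d[f"CTD_C_{attr}_g{g + 1}"] == pytest.approx(
                        labs.count(g) / len(s), abs=1e-9
                    )
                for a, b in ((0, 1), (0, 2), (1, 2)):
                    n = sum(
                        1
                        for x, y in zip(labs, labs[1:])
                        if {x, y} == {a, b}
                    )
                    assert d[f"CTD_T_{attr}_g{a + 1}g{b + 1}"] == pytest.approx(
                        n / (len(s) - 1), abs=1e-9
                    )


# ---------------------------------------------------------------------------
# sequence order
# ---------------------------------------------------------------------------

class TestOrder:
    def test_toy_distance_matrix(self):
        dm = np.zeros((20, 20))
        dm[IDX["A"], IDX["R"]] = dm[IDX["R"], IDX["A"]] = 1.0
        v = order_features(rec("ARAR"), maxlag=2, matrices={"toy": dm})
        d = dict(zip(v.names, v.values))
        assert d["SOC_toy_d1"] == 3.0
        assert d["SOC_toy_d2"] == 0.0

    def test_homopolymer_all_zero_coupling(self):
        v = order_features(rec("A" * 40), maxlag=5)
        d = dict(zip(v.names, v.values))
        assert all(v == 0 for k, v in d.items() if k.startswith("SOC"))
        assert all(v == 0 for k, v in d.items() if k.startswith("QSO") and "_d" in k)

    def test_dimensionality(self, rng):
        v = order_features(rec(random_seq(rng)), maxlag=30)
        assert len(v) == 60 + 100

    def test_matches_brute_force(self, rng):
        matrices = default_distance_matrices()
        w = 0.1
        for _ in range(20):
            s = random_seq(rng)
            L = len(s)
            v = order_features(rec(s), maxlag=6, weight=w, matrices=matrices)
            d = dict(zip(v.names, v.values))
            for mname, dm in matrices.items():
                taus = []
                for lag in range(1, 7):
                    taus.append(
                        sum(dm[IDX[s[i]], IDX[s[i + lag]]] ** 2 for i in range(L - lag))
                    )
                denom = 1 + w * sum(taus)
                for lag, tau in enumerate(taus, start=1):
                    assert d[f"SOC_{mname}_d{lag}"] == pytest.approx(tau, abs=1e-9)
                    assert d[f"QSO_{mname}_d{lag}"] == pytest.approx(w * tau / denom, abs=1e-9)
                for r in ALPHABET:
                    assert d[f"QSO_{mname}_{r}"] == pytest.approx(
                        s.count(r) / L / denom, abs=1e-9
                    )


# ---------------------------------------------------------------------------
# APAAC
# ---------------------------------------------------------------------------

class TestAPAAC:
    def test_dimensionality(self, rng):
        assert len(apaac_features(rec(random_seq(rng)), lam=30, weight=0.05)) == 80

    def test_weight_zero_reduces_to_aac(self, rng):
        s = random_seq(rng)
        v = apaac_features(rec(s), lam=30, weight=0.0)
        aac = composition_features(rec(s)).values[:20]
        np.testing.assert_allclose(v.values[:20], aac, atol=1e-12)
        assert np.all(v.values[20:] == 0)

    def test_denominator_identity(self, rng):
        """First-20 block mass equals 1/(1 + w*sum(tau)), recomputed directly."""
        w = 0.05
        for _ in range(10):
            s = random_seq(rng)
            v = apaac_features(rec(s), lam=10, weight=w)
            from dtiforge.aadata import (
                PSEAAC_HYDROPHILICITY,
                PSEAAC_HYDROPHOBICITY,
                standardize_scale,
            )

            h1 = standardize_scale(PSEAAC_HYDROPHOBICITY)
            h2 = standardize_scale(PSEAAC_HYDROPHILICITY)
            L = len(s)
            taus = []
            for j in range(1, 11):
                taus.append(sum(h1[s[i]] * h1[s[i + j]] for i in range(L - j)) / (L - j))
                taus.append(sum(h2[s[i]] * h2[s[i + j]] for i in range(L - j)) / (L - j))
            denom = 1 + w * sum(taus)
            assert v.values[:20].sum() == pytest.approx(1 / denom, abs=1e-9)
            assert v.values.sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# averaged properties
# ---------------------------------------------------------------------------

class TestAAProp:
    def test_homopolymer_gives_property_value(self):
        scales = aaprop_scales()
        v = aaprop_features(rec("AAA"))
        d = dict(zip(v.names, v.values))
        for name, scale in scales.items():
            assert d[f"AAPROP_{name}"] == pytest.approx(standardize_scale(scale)["A"])

    def test_default_size_and_symmetry(self):
        v = aaprop_features(rec("AR" * 20))
        assert len(v) == 33
        p = PropertyTable("pm", {r: (1.0 if r == "A" else -1.0 if r == "R" else 0.0) for r in ALPHABET},
                          standardized=True)
        assert aaprop_features(rec("AR"), [p]).values[0] == pytest.approx(0.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ConfigError):
            aaprop_features(rec("AAA"), [])


# ---------------------------------------------------------------------------
# full profile
# ---------------------------------------------------------------------------

class TestProfile:
    def test_default_total_is_1080(self, rng):
        for _ in range(5):
            v = featurize_protein(rec(random_seq(rng, lo=31, hi=500)))
            assert len(v) == 1080
            assert np.isfinite(v.values).all()
            assert len(set(v.names)) == 1080

    def test_determinism_and_id_invariance(self, rng):
        s = random_seq(rng)
        a = featurize_protein(ProteinRecord("a", s))
        b = featurize_protein(ProteinRecord("b", s))
        np.testing.assert_array_equal(a.values, b.values)

    def test_composition_only_profile(self):
        profile = DescriptorProfile(
            autocorrelation_kind=None, ctd=False, order_maxlag=None,
            apaac_lam=None, aaprop=False, declared_total=420,
        )
        assert len(featurize_protein(rec("ACDA"), profile)) == 420

    def test_family_error_names_family(self):
        with pytest.raises(SequenceError, match=r"\[autocorrelation\]"):
            featurize_protein(rec("ACDA"))

    def test_declared_total_mismatch_rejected(self):
        with pytest.raises(ConfigError, match="declares"):
            DescriptorProfile(declared_total=999)

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "profile.yaml"
        DescriptorProfile().to_yaml(p)
        loaded = DescriptorProfile.from_yaml(p)
        assert loaded == DescriptorProfile()
        data = yaml.safe_load(p.read_text())
        data["bogus_key"] = 1
        p.write_text(yaml.safe_dump(data))
        with pytest.raises(ConfigError, match="bogus_key"):
            DescriptorProfile.from_yaml(p)

    def test_min_sequence_length(self):
        assert DescriptorProfile().min_sequence_length() == 31
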