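"""Conformation parameters, physicochemical lookups, window encoding."""

import numpy as np
import pytest

from sspipe import (
    ConformationTable,
    ProteinChain,
    SimSpec,
    StructureString,
    WindowEncoder,
    compute_conformation_parameters,
    encode_windows,
    feature_dimension,
    lookup_physico,
    normalize_profile,
    published_conformation_table,
    simulate,
    synthesize_pssm,
)
from sspipe.features import NET_CHARGE, HYDROPATHY, SIDE_CHAIN_MASS
from sspipe.pssm import CANONICAL_ORDER
from sspipe.sequences import THREE_STATES

#: reference (window size, feature count) pairs for the supported windows
EXPECTED_DIMS = {7: 146, 9: 186, 11: 226, 13: 266, 15: 306, 17: 346, 19: 386}


class TestConformation:
    def test_hand_counted_single_pair(self):
        ct = compute_conformation_parameters(
            [(ProteinChain("c", "AAA"), StructureString("HHC"))]
        )
        np.testing.assert_allclose(ct.row("A"), [2 / 3, 0, 1 / 3])
        for res in CANONICAL_ORDER.replace("A", ""):
            np.testing.assert_allclose(ct.row(res), [1 / 3] * 3)
            assert ct.flagged_uniform[CANONICAL_ORDER.index(res)]

    def test_published_table_fixture(self):
        ct = published_conformation_table()
        np.testing.assert_allclose(ct.row("A"), [0.49, 0.16, 0.35], atol=1e-9)
        np.testing.assert_allclose(ct.row("V"), [0.30, 0.41, 0.29], atol=1e-9)

    def test_rows_sum_to_one(self):
        ct = published_conformation_table()
        np.testing.assert_allclose(ct.S.sum(axis=1), np.ones(20), atol=1e-9)

    def test_counts_consistent_with_proportions(self):
        ct = compute_conformation_parameters(
            [(ProteinChain("c", "AVAVA"), StructureString("HHECC"))]
        )
        nz = ct.totals > 0
        np.testing.assert_array_equal(
            np.rint(ct.S[nz] * ct.totals[nz, None]).astype(int), ct.counts[nz]
        )

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            compute_conformation_parameters([])

    def test_length_mismatch_names_chain(self):
        with pytest.raises(ValueError, match="'bad'"):
            compute_conformation_parameters(
                [(ProteinChain("bad", "AAA"), StructureString("HH"))]
            )

    def test_parameter_recovery_from_simulation(self):
        """Recomputing S_ij = a_ij/a_i on simulated residues matches the
        posterior implied by the generator's emission matrix and class
        marginals to within 0.02 — the sample is sized so that bound is a
        >= 3-sigma binomial envelope for the rarest amino acid."""
        spec = SimSpec(n_chains=3300, length_range=(40, 60), seed=5)
        data = simulate(spec)
        n_residues = sum(len(c) for c, _, _ in data)
        assert n_residues >= 50_000
        ct = compute_conformation_parameters([(c, s) for c, s, _ in data])
        emission = spec.emission_matrix()  # 3 x 20, P(res | class)
        all_states = "".join(s.states for _, s, _ in data)
        marginals = np.array(
            [all_states.count(s) / len(all_states) for s in THREE_STATES]
        )
        joint = emission * marginals[:, None]  # 3 x 20
        expected = (joint / joint.sum(axis=0, keepdims=True)).T  # 20 x 3
        assert np.max(np.abs(ct.S - expected)) < 0.02


class TestPhysico:
    @pytest.mark.parametrize(
        "residue, charge", [("R", 1), ("D", -1), ("H", 1), ("K", 1), ("E", -1), ("A", 0)]
    )
    def test_net_charges(self, residue, charge):
        assert lookup_physico(residue)[0] == charge

    def test_hydropathy_extremes(self):
        assert lookup_physico("I")[1] == 4.5
        assert lookup_physico("R")[1] == -4.5

    def test_side_chain_masses(self):
        assert lookup_physico("G")[2] == 1.0079
        assert lookup_physico("W")[2] == 130.1689

    def test_tables_complete(self):
        for table in (NET_CHARGE, HYDROPATHY, SIDE_CHAIN_MASS):
            assert set(table) == set(CANONICAL_ORDER)

    def test_unknown_residue_policies(self):
        assert lookup_physico("X") == (0.0, 0.0, 0.0)
        with pytest.raises(KeyError):
            lookup_physico("X", strict=True)


def _encoded(chain, ws, seed=9, ct=None):
    prof = normalize_profile(synthesize_pssm(chain, 0.9, seed))
    return encode_windows(
        chain, prof, ct or published_conformation_table(), window_size=ws
    )


class TestEncoding:
    @pytest.mark.parametrize("ws, dim", sorted(EXPECTED_DIMS.items()))
    def test_feature_dimension_per_window_size(self, ws, dim):
        chain = ProteinChain("c", "MFKVYGYDSNIHKCVYCDNAKRLL")
        X = _encoded(chain, ws)
        assert feature_dimension(ws) == dim
        assert X.shape == (len(chain), dim)

    def test_all_entries_in_unit_interval(self):
        X = _encoded(ProteinChain("c", "MFKVYGYDSNIHKCVYCDNAKRLL"), 13)
        assert X.min() >= 0.0 and X.max() <= 1.0

    def test_single_residue_chain_is_all_padding_except_centre(self):
        chain = ProteinChain("c", "M")
        X = _encoded(chain, 7)
        row = X[0, :140].reshape(7, 20)
        assert np.all(row[:3] == 0) and np.all(row[4:] == 0)

    def test_translation_consistency(self):
        """The PSSM block of residue i at offset n equals the block of
        residue i+n at offset 0 (the centre block)."""
        chain = ProteinChain("c", "MFKVYGYDSNIHKCVYCDNAKRLLTVKKQPFE")
        ws, half = 13, 6
        X = _encoded(chain, ws)
        centre = slice(half * 20, (half + 1) * 20)
        for i in range(len(chain)):
            for n in (-3, 1, 5):
                j = i + n
                if 0 <= j < len(chain):
                    block = X[i, (half + n) * 20 : (half + n + 1) * 20]
                    np.testing.assert_array_equal(block, X[j, centre])

    def test_central_scalars_layout(self):
        """Last 6 features are the centre residue's propensities and scaled
        charge, hydropathy, mass."""
        ct = published_conformation_table()
        chain = ProteinChain("c", "RRRRRRRR")
        X = _encoded(chain, 7, ct=ct)
        np.testing.assert_allclose(X[0, -6:-3], ct.row("R"))
        assert X[0, -3] == 1.0  # charge +1 -> 1
        assert X[0, -2] == pytest.approx(0.0)  # hydropathy -4.5 -> 0
        assert X[0, -1] == pytest.approx((100.1431 - 1.0079) / (130.1689 - 1.0079))

    def test_odd_window_required(self):
        with pytest.raises(ValueError):
            feature_dimension(8)
        with pytest.raises(ValueError):
            feature_dimension(21)

    def test_profile_must_be_normalized(self):
        chain = ProteinChain("c", "MFKVYGY")
        raw = synthesize_pssm(chain, 0.9, 1)
        with pytest.raises(ValueError, match="normalized"):
            encode_windows(chain, raw, published_conformation_table())

    def test_encoder_estimator_interface(self, small_dataset):
        pairs = [(c, s) for c, s, _ in small_dataset[:6]]
        profiles = {
            c.id: normalize_profile(p) for c, _, p in small_dataset[:6]
        }
        enc = WindowEncoder(window_size=9)
        assert enc.get_params()["window_size"] == 9
        enc.fit(pairs)
        X = enc.transform([c for c, _ in pairs], profiles)
        assert X.shape == (sum(len(c) for c, _ in pairs), 186)
        assert enc.n_features_out_ == 186
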