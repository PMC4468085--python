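"""Energy-term closed forms, MM-GBSA bookkeeping and alanine scanning."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from kinnet import energetics as en
from kinnet import synthetic_data as sd
from kinnet.structio import Atom, ConformationalEnsemble, Residue, Structure


@pytest.fixture
def params():
    return en.EnergyModelParams()


def pair_structure(d, q1=0.0, q2=0.0, element="C", radius=1.7):
    a = Atom(1, "L1", element, 0, [0.0, 0, 0], True, radius, partial_charge=q1)
    b = Atom(2, "L2", element, 0, [d, 0.0, 0], True, radius, partial_charge=q2)
    return Structure(
        [Residue("A", 1, "LIG", [a], is_ligand=True),
         Residue("B", 1, "LIG", [b], is_ligand=True)]
    )


class TestEnergyTerms:
    def test_lj_minimum_value(self, params):
        rmin = 2 * params.lj_rmin_half["C"]
        dec = en.energy_terms(pair_structure(rmin), params)
        assert dec.e_vdw == pytest.approx(-params.lj_eps["C"], abs=1e-12)

    def test_coulomb_constant(self, params):
        dec = en.energy_terms(pair_structure(10.0, 1.0, -1.0), params)
        assert dec.e_elec == pytest.approx(-33.206, abs=1e-9)

    def test_nonpolar_term_is_sigma_times_sasa(self, params):
        dec = en.energy_terms(pair_structure(30.0), params)
        area = dec.g_solv_np / params.sigma_np
        # two isolated C spheres
        expected = 2 * 4 * np.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(expected, rel=0.01)
        assert 0.0072 * 1000.0 == pytest.approx(7.2)

    def test_unparameterized_atom_named(self, params):
        s = pair_structure(5.0)
        s.residues[0].atoms[0].element = "SE"
        s.residues[0].atoms[0].radius = 1.9
        with pytest.raises(KeyError, match="L1"):
            en.energy_terms(s, params)

    def test_gb_sign_for_charged_atom(self, params):
        s = pair_structure(50.0, q1=1.0)
        dec = en.energy_terms(s, params)
        assert dec.g_solv_elec < 0  # solvation of a charge is favourable


class TestMMGBSA:
    def test_eq1_identity_every_run(self, holo_static_ensemble, params):
        bfe = en.mmgbsa(holo_static_ensemble, params)
        assert bfe.dg_bind == pytest.approx(bfe.dg_mm + bfe.dg_solv - bfe.t_ds,
                                            abs=1e-9)

    def test_per_frame_mean_matches_total(self, params):
        _, holo = sd.gen_complex(sd.ComplexSpec(seed=3))
        ens = sd.gen_ensemble(holo, 6, [(6, 0.2)], seed=1)
        bfe = en.mmgbsa(ens, params)
        assert bfe.per_frame["dG_frame"].mean() == pytest.approx(
            bfe.dg_mm + bfe.dg_solv, abs=1e-12
        )

    def test_noninteracting_limit(self, params):
        _, holo = sd.gen_complex(sd.ComplexSpec(bridge_strength=0, seed=2))
        ens = ConformationalEnsemble(topology=holo, frames=holo.coords()[None])
        bfe = en.mmgbsa(ens, params)
        assert abs(bfe.per_frame["dE_vdw"][0]) + abs(bfe.per_frame["dE_elec"][0]) < 1e-3

    def test_charge_doubling_quadruples_delta_elec(self):
        _, holo = sd.gen_complex(sd.ComplexSpec(seed=4))
        q1 = {("LEU", "CB2"): 0.2, ("LIG", "L1"): -0.2, ("LIG", "L2"): -0.2,
              ("LIG", "L3"): -0.2, ("LIG", "L4"): -0.2}
        q2 = {k: 2 * v for k, v in q1.items()}
        ens = ConformationalEnsemble(topology=holo, frames=holo.coords()[None])
        e1 = en.mmgbsa(ens, en.EnergyModelParams(charges=q1)).per_frame["dE_elec"][0]
        e2 = en.mmgbsa(ens, en.EnergyModelParams(charges=q2)).per_frame["dE_elec"][0]
        assert e2 == pytest.approx(4 * e1, rel=1e-9)

    def test_missing_ligand_errors(self, helix10, params):
        ens = ConformationalEnsemble(topology=helix10,
                                     frames=helix10.coords()[None])
        with pytest.raises(ValueError, match="ligand"):
            en.mmgbsa(ens, params)


class TestAlanineScan:
    def test_alanine_self_scan_zero(self, params):
        _, holo = sd.gen_complex(sd.ComplexSpec(seed=1))
        holo.protein_residues()[0].res_type = "ALA"
        ens = ConformationalEnsemble(topology=holo, frames=holo.coords()[None])
        scan = en.alanine_scan(ens, ["A:1"], params)
        assert scan.table.loc["A:1", "ddG"] == 0.0

    def test_glycine_proline_skipped(self, params):
        _, holo = sd.gen_complex(sd.ComplexSpec(seed=1))
        holo.protein_residues()[2].res_type = "GLY"
        holo.protein_residues()[3].res_type = "PRO"
        ens = ConformationalEnsemble(topology=holo, frames=holo.coords()[None])
        scan = en.alanine_scan(ens, ["A:3", "A:4"], params)
        assert set(scan.skipped) == {"A:3", "A:4"}
        assert scan.table.empty

    def test_breakdown_sums_to_total(self, holo_static_ensemble, params):
        scan = en.alanine_scan(holo_static_ensemble, ["A:1", "A:5"], params)
        for _, row in scan.table.iterrows():
            parts = row[["ddE_vdw", "ddE_elec", "ddG_np", "ddG_gb"]].sum()
            assert row["ddG"] == pytest.approx(parts, abs=1e-9)

    def test_single_contact_bookkeeping_oracle(self, params):
        """ddG of an isolated side-chain/ligand contact equals the direct
        term-difference computed by hand from the decompositions."""
        _, holo = sd.gen_complex(sd.ComplexSpec(seed=6))
        ens = ConformationalEnsemble(topology=holo, frames=holo.coords()[None])
        scan = en.alanine_scan(ens, ["A:1"], params, max_steps=0)

        # oracle: recompute the four deltas wild-type and truncated (the
        # hydrogen placed exactly at the truncation geometry, no relaxation)
        def deltas(structure):
            c = en.energy_terms(structure, params, "complex")
            p = en.energy_terms(structure, params, "protein")
            l = en.energy_terms(structure, params, "ligand")
            return np.array(
                [c.e_vdw - p.e_vdw - l.e_vdw,
                 c.e_elec - p.e_elec - l.e_elec,
                 c.g_solv_np - p.g_solv_np - l.g_solv_np,
                 c.g_solv_elec - p.g_solv_elec - l.g_solv_elec]
            )

        mut = en._truncate_to_alanine(holo, "A:1")
        expected = deltas(mut) - deltas(holo)
        got = scan.table.loc[
            "A:1", ["ddE_vdw", "ddE_elec", "ddG_np", "ddG_gb"]
        ].to_numpy(dtype=float)
        assert np.abs(got - expected).max() < 1e-6

    def test_distal_residue_negligible(self, holo_static_ensemble, params):
        scan = en.alanine_scan(holo_static_ensemble, ["A:6"], params)
        assert abs(scan.table.loc["A:6", "ddG"]) < 0.05

    def test_rigid_body_invariance(self):
        """ddG is exact under rotation up to the SASA quadrature error."""
        params = en.EnergyModelParams(sasa_points=960)
        _, holo = sd.gen_complex(sd.ComplexSpec(seed=2))
        rot = Rotation.from_euler("xyz", [0.3, 1.1, -0.7])
        moved = holo.copy()
        moved.set_coords(rot.apply(holo.coords()) + np.array([3.0, -2.0, 8.0]))
        e1 = en.alanine_scan(
            ConformationalEnsemble(topology=holo, frames=holo.coords()[None]),
            ["A:1"], params,
        ).table.loc["A:1", "ddG"]
        e2 = en.alanine_scan(
            ConformationalEnsemble(topology=moved, frames=moved.coords()[None]),
            ["A:1"], params,
        ).table.loc["A:1", "ddG"]
        # the MM terms are exactly invariant; the residual is the
        # orientation dependence of the finite SASA quadrature
        assert e1 == pytest.approx(e2, abs=5e-3)

    def test_hotspot_recovery_over_seeds(self, params):
        """Pocket residues outrank distal residues in |ddG| (planted truth)."""
        wins = 0
        for seed in range(10):
            _, holo = sd.gen_complex(sd.ComplexSpec(seed=seed))
            ens = ConformationalEnsemble(topology=holo,
                                         frames=holo.coords()[None])
            scan = en.alanine_scan(ens, ["A:1", "A:12", "A:5", "A:6"], params)
            t = scan.table["ddG"].abs()
            wins += min(t["A:1"], t["A:12"]) > max(t["A:5"], t["A:6"])
        assert wins >= 9


class TestEntropy:
    def test_single_atom_no_vibrations(self, params):
        s = Structure([Residue("A", 1, "LIG",
                               [Atom(1, "L1", "C", 0, [0, 0, 0], True, 1.7)],
                               is_ligand=True)])
        res = en.entropy_terms(s, params)
        assert res.s_vib == 0.0
        assert res.s_trans > 0

    def test_diatomic_matches_harmonic_closed_form(self, params):
        """One bond-stretch mode: S_vib equals the textbook HO entropy."""
        a = Atom(1, "C1", "C", 0, [0, 0, 0], True, 1.7)
        b = Atom(2, "C2", "C", 0, [1.53, 0, 0], True, 1.7)
        s = Structure([Residue("A", 1, "LIG", [a, b], is_ligand=True)])
        res = en.entropy_terms(s, params)
        mu = 12.011 / 2
        omega = np.sqrt(2 * en.BOND_FORCE_CONSTANT * en._FREQ_SQ_SI / mu)
        x = en._HBAR * omega / (en._KB_J * 300.0)
        expected = en.KB_KCAL * (x / np.expm1(x) - np.log(-np.expm1(-x)))
        assert res.s_vib == pytest.approx(expected, abs=1e-9)

    def test_mass_scaling_of_frequency(self, params):
        """Doubling the mass at fixed k lowers the frequency by sqrt(2)."""
        def s_vib_for(mass_element):
            a = Atom(1, "C1", mass_element, 0, [0, 0, 0], True, 1.7)
            b = Atom(2, "C2", mass_element, 0, [1.53, 0, 0], True, 1.7)
            s = Structure([Residue("A", 1, "LIG", [a, b], is_ligand=True)])
            return en.entropy_terms(s, params).s_vib

        # sulfur is ~2.67x carbon mass; verify via the closed form instead
        def closed(mass):
            mu = mass / 2
            omega = np.sqrt(2 * en.BOND_FORCE_CONSTANT * en._FREQ_SQ_SI / mu)
            x = en._HBAR * omega / (en._KB_J * 300.0)
            return en.KB_KCAL * (x / np.expm1(x) - np.log(-np.expm1(-x)))

        assert s_vib_for("S") == pytest.approx(closed(32.06), abs=1e-9)
        assert s_vib_for("S") > s_vib_for("C")  # softer mode, more entropy

    def test_unminimized_structure_rejected(self, params):
        # non-bonded atoms on the repulsive LJ slope: negative tangential
        # curvature gives extra unstable modes beyond the rigid-body six
        pts = [[0.0, 0, 0], [2.5, 0, 0], [2.5, 2.5, 0], [0.0, 2.5, 0]]
        residues = [
            Residue("A", k + 1, "LIG",
                    [Atom(k + 1, f"L{k}", "C", k, p, True, 1.7)], is_ligand=True)
            for k, p in enumerate(pts)
        ]
        with pytest.raises(ValueError, match="not minimized"):
            en.entropy_terms(Structure(residues), params)


class TestDecompositionInvariants:
    def test_finite_required(self):
        with pytest.raises(ValueError):
            en.EnergyDecomposition(np.inf, 0, 0, 0, 0)

    def test_binding_identity_enforced(self):
        with pytest.raises(ValueError):
            en.BindingFreeEnergy(1.0, 0.0, 0.0, 0.0, None, pd.DataFrame(), 1)
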