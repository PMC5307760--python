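"""Network ingestion, stoichiometry, control-affine realisation, export."""

import numpy as np
import pytest
import sympy as sp

import crnreduce as cr
from crnreduce.errors import (
    AffineDecompositionError,
    SBMLParseError,
    UnsupportedFeatureError,
)

from conftest import linear_system, make_ab_network, make_decay_system, make_enzyme_network

MINIMAL_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
 <model id="m">
  <listOfCompartments>
   <compartment id="cell" size="1" constant="true"/>
  </listOfCompartments>
  <listOfSpecies>
   <species id="A" compartment="cell" initialConcentration="1" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
   <species id="B" compartment="cell" initialConcentration="0" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
  </listOfSpecies>
  <listOfParameters>
   <parameter id="k" value="0.5" constant="true"/>
  </listOfParameters>
  <listOfReactions>
   <reaction id="r1" reversible="false" fast="false">
    <listOfReactants><speciesReference species="A" stoichiometry="1" constant="true"/></listOfReactants>
    <listOfProducts><speciesReference species="B" stoichiometry="1" constant="true"/></listOfProducts>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><times/><ci>k</ci><ci>A</ci></apply>
     </math>
    </kineticLaw>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""


class TestLoadSBML:
    def test_minimal_mass_action_document(self):
        net = cr.load_sbml(MINIMAL_SBML)
        assert net.species_ids == ["A", "B"]
        assert len(net.reactions) == 1
        assert net.parameters == {"k": 0.5}
        rate = net.reactions[0].rate
        assert sp.simplify(rate - sp.Symbol("k") * sp.Symbol("A")) == 0

    def test_truncated_document_is_a_parse_error(self):
        with pytest.raises(SBMLParseError):
            cr.load_sbml(MINIMAL_SBML[: len(MINIMAL_SBML) // 2])

    def test_missing_kinetic_law_is_unsupported(self):
        text = MINIMAL_SBML.replace(
            MINIMAL_SBML[MINIMAL_SBML.index("<kineticLaw>"):
                         MINIMAL_SBML.index("</kineticLaw>") + len("</kineticLaw>")],
            "",
        )
        with pytest.raises(UnsupportedFeatureError, match="kinetic law"):
            cr.load_sbml(text)

    def test_events_are_rejected_by_name(self):
        text = MINIMAL_SBML.replace(
            "</listOfReactions>",
            '</listOfReactions><listOfEvents><event useValuesFromTriggerTime="true">'
            '<trigger initialValue="true" persistent="true">'
            '<math xmlns="http://www.w3.org/1998/Math/MathML"><true/></math>'
            "</trigger></event></listOfEvents>",
        )
        with pytest.raises(UnsupportedFeatureError, match="event"):
            cr.load_sbml(text)

    def test_network_sbml_round_trip_preserves_dynamics(self, phosphorelay):
        net, spec, system = phosphorelay
        net2 = cr.load_sbml(cr.network_to_sbml(net))
        assert net2.n_species == net.n_species
        assert len(net2.reactions) == len(net.reactions)
        sys2 = cr.build_state_space(net2, spec)
        t1 = cr.simulate(system, t_end=2.0)
        t2 = cr.simulate(sys2, t_end=2.0)
        assert np.allclose(t1.states, t2.states, rtol=1e-9, atol=1e-12)


class TestStoichiometry:
    def test_single_conversion_column(self):
        N = cr.stoichiometry_matrix(cr.load_sbml(MINIMAL_SBML))
        assert N.tolist() == [[-1], [1]]

    def test_enzyme_mechanism_net_columns(self):
        N = cr.stoichiometry_matrix(make_enzyme_network())
        # columns: E+S<->C (net) and C->E+P, species order E,S,C,P
        assert N.T.tolist() == [[-1, -1, 1, 0], [1, 0, -1, 1]]

    def test_empty_reaction_list(self):
        net = cr.ReactionNetwork([cr.Species("A", 1.0)], [], {})
        assert cr.stoichiometry_matrix(net).shape == (1, 0)


class TestNetworkValidation:
    def test_duplicate_species_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cr.ReactionNetwork([cr.Species("A", 1.0), cr.Species("A", 2.0)], [], {})

    def test_negative_initial_concentration_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            cr.Species("A", -1.0)

    def test_undeclared_rate_identifier_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            cr.ReactionNetwork(
                [cr.Species("A", 1.0)],
                [cr.Reaction("r", {"A": 1}, {}, "k_missing*A")],
                {},
            )


class TestBuildStateSpace:
    def test_decay_with_additive_input(self):
        _, _, system = make_decay_system(k=1.0, k_in=1.0)
        # f(x) = -k x, g = 1, h = x
        assert np.allclose(system.f([3.0]), [-3.0])
        assert np.allclose(system.g([3.0]), [[1.0]])
        assert np.allclose(system.h([3.0]), [3.0])
        assert system.u0 == pytest.approx([1.0])

    def test_parameter_scale_input_baseline_is_one(self):
        net = make_ab_network()
        spec = cr.InputOutputSpec([("k1", "parameter-scale")], "B")
        system = cr.build_state_space(net, spec)
        assert system.u0 == pytest.approx([1.0])
        # rhs at u0 reproduces the nominal model
        nominal = cr.build_state_space(net, cr.InputOutputSpec([], "B"))
        x = np.array([1.3, 0.7])
        assert np.allclose(system.rhs(x), nominal.rhs(x))

    def test_unknown_species_in_spec_rejected(self):
        net = make_ab_network()
        with pytest.raises(ValueError, match="unknown species"):
            cr.build_state_space(net, cr.InputOutputSpec([], "A + Missing"))

    def test_nonlinear_input_rejected(self):
        A = sp.Symbol("A")
        net = cr.ReactionNetwork(
            [cr.Species("A", 1.0)],
            [cr.Reaction("r", {"A": 1}, {}, sp.Symbol("k") ** 2 * A)],
            {"k": 2.0},
        )
        with pytest.raises(AffineDecompositionError):
            cr.build_state_space(net, cr.InputOutputSpec([("k", "parameter-scale")], "A"))

    def test_jacobian_matches_finite_differences_at_random_states(self, phosphorelay):
        _, _, system = phosphorelay
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.uniform(0.05, 2.0, system.n)
            J = system.jac(x)
            Jfd = np.zeros_like(J)
            h = 1e-6 * (1 + np.abs(x))
            for j in range(system.n):
                xp, xm = x.copy(), x.copy()
                xp[j] += h[j]
                xm[j] -= h[j]
                Jfd[:, j] = (system.rhs(xp) - system.rhs(xm)) / (2 * h[j])
            assert np.max(np.abs(J - Jfd)) / np.max(np.abs(J)) < 1e-4

    def test_mass_action_drift_respects_conservation(self, phosphorelay):
        net, _, system = phosphorelay
        gamma = cr.left_null_space(cr.stoichiometry_matrix(net))
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.uniform(0.1, 2.0, system.n)
            assert np.max(np.abs(gamma @ system.f(x))) < 1e-10
            assert np.max(np.abs(gamma @ system.rhs(x, [1.7]))) < 1e-10


class TestExport:
    def test_identity_reduction_round_trips_through_sbml(self, phosphorelay):
        _, _, system = phosphorelay
        n = system.n
        identity = cr.galerkin_reduce(system, np.eye(n), np.eye(n))
        net2 = cr.load_sbml(cr.export_model(identity, "sbml"))
        sys2 = cr.build_state_space(net2, cr.InputOutputSpec([], net2.species_ids[0]))
        t1 = cr.simulate(identity, t_end=3.0)
        t2 = cr.simulate(sys2, t_end=3.0)
        assert np.max(np.abs(t1.states - t2.states)) < 1e-6

    def test_lumped_sbml_has_lump_membership_annotation(self, phosphorelay):
        _, _, system = phosphorelay
        L = cr.pair_lumping_matrix(system.n, 0, 1)
        lumped = cr.galerkin_reduce(system, L, cr.moore_penrose_inverse(L))
        text = cr.export_model(lumped, "sbml")
        assert f"{system.names[0]}+{system.names[1]}" in text
        assert cr.load_sbml(text).n_species == system.n - 1

    def test_truncated_json_metadata_reconstructs_hankel_values(self):
        import json

        import scipy.linalg

        fx = cr.make_lti(7, 4)
        tf = cr.balancing_transform(fx.analytic_P, fx.analytic_Q, 2)
        sysl = fx.to_system()
        red = cr.truncate(sysl, tf)
        text = cr.export_model(
            red, "json",
            metadata={"hankel": tf.hankel, "P": fx.analytic_P, "Q": fx.analytic_Q},
        )
        meta = json.loads(text)["metadata"]
        P = np.array(meta["P"])
        Q = np.array(meta["Q"])
        Lc = scipy.linalg.cholesky(P)
        Ro = scipy.linalg.cholesky(Q)
        s = scipy.linalg.svdvals(Lc @ Ro.T)
        assert np.allclose(s[:2], meta["hankel"], rtol=1e-8)

    def test_json_round_trip_preserves_dynamics(self, phosphorelay):
        _, _, system = phosphorelay
        L = cr.pair_lumping_matrix(system.n, 2, 4)
        lumped = cr.galerkin_reduce(system, L, cr.moore_penrose_inverse(L))
        again = cr.import_model(cr.export_model(lumped, "json"))
        t1 = cr.simulate(lumped, t_end=3.0)
        t2 = cr.simulate(again, t_end=3.0)
        assert np.max(np.abs(t1.states - t2.states)) < 1e-9

    def test_unknown_format_rejected(self):
        system = linear_system([[-1.0]])
        with pytest.raises(ValueError, match="format"):
            cr.export_model(system, "matlab")
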