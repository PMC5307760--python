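#!/usr/bin/env python
"""Run the combined reduction on an externally supplied SBML model.

This is the accession-dependent companion script for published case-study
models (e.g. a receptor-signalling model downloaded from the BioModels
database): supply the SBML file, the input declaration and the output
expression and it prints the per-stage dimension / error / stiffness table
plus the importance indices, and writes the reduced model.

Because such models must be obtained separately, this script is not part
of the test suite.

Examples
--------
Chemotaxis-style run (attractant input scaling a binding rate, total
phosphorylated response regulator as output)::

    python scripts/reduce_case_study.py --sbml model.xml \
        --input k_bind:parameter-scale \
        --output "YP + A_YP + YP_Z" \
        --t-end 3.0 --u-step 2.0 --report out/

A model whose accumulating species needs an added depletion rate first
(exposed as a parameter because the published modification does not state
its value)::

    python scripts/reduce_case_study.py --sbml BIOMD0000000049.xml \
        --deplete ProteasomeTotal:0.01 \
        --input EGF_binding_rate:parameter-scale \
        --output "ppERK + dppERK + ppERK_MKP3 + dppERK_MKP3" \
        --pert-low 0.4 --pert-high 1.6 --report out/
"""

import argparse
import os
import sys

import numpy as np
import sympy as sp

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import crnreduce as cr  # noqa: E402
from crnreduce.model_core import Reaction  # noqa: E402


def add_depletion(network, species_id, rate_constant):
    """Append a first-order depletion reaction for a species (used to make
    models with an accumulating pool asymptotically stable)."""
    pid = f"k_deplete_{species_id}"
    network.parameters[pid] = float(rate_constant)
    network.reactions.append(
        Reaction(
            f"deplete_{species_id}", {species_id: 1}, {},
            sp.Symbol(pid) * sp.Symbol(species_id),
        )
    )
    return network


def main():
    parser = argparse.ArgumentParser(
        description=__doc__, formatter_class=argparse.RawDescriptionHelpFormatter
    )
    parser.add_argument("--sbml", required=True)
    parser.add_argument("--input", dest="inputs", action="append", required=True,
                        help="ID[:mode]; mode = parameter-scale | additive-rate")
    parser.add_argument("--output", required=True)
    parser.add_argument("--max-error", type=float, default=0.05)
    parser.add_argument("--chi-c", type=float, default=250.0)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--t-end", type=float, default=10.0)
    parser.add_argument("--u-step", type=float, default=None,
                        help="validation input level (default 1.5x baseline)")
    parser.add_argument("--pert-low", type=float, default=0.2)
    parser.add_argument("--pert-high", type=float, default=1.8)
    parser.add_argument("--deplete", default=None,
                        help="SPECIES:RATE — add a first-order depletion reaction")
    parser.add_argument("--no-nondim", action="store_true")
    parser.add_argument("--report", required=True)
    args = parser.parse_args()

    network = cr.load_sbml(args.sbml)
    if args.deplete:
        sid, _, rate = args.deplete.partition(":")
        add_depletion(network, sid, float(rate or 0.01))
    inputs = []
    for item in args.inputs:
        ident, _, mode = item.partition(":")
        inputs.append((ident, mode or "parameter-scale"))
    spec = cr.InputOutputSpec(inputs=inputs, output_expression=args.output)
    system = cr.build_state_space(network, spec)
    print(f"model: {system.n} states, {len(network.reactions)} reactions, "
          f"chi(x0) = {cr.stiffness_coefficient(system):.4g}")

    if args.u_step is None:
        u = 1.5 * np.where(system.u0 != 0, system.u0, 1.0)
    else:
        u = np.full(system.l, args.u_step)
    config = cr.ReductionConfig(
        max_error=args.max_error,
        chi_c=args.chi_c,
        seed=args.seed,
        protocol=cr.Protocol(u=u, t_end=args.t_end),
        pert_low=args.pert_low,
        pert_high=args.pert_high,
        apply_nondim=not args.no_nondim,
    )
    report = cr.run_combined_reduction(network, spec, config)
    print(report.summary())
    if report.indices is not None:
        print(report.indices.to_frame().to_string(index=False))

    os.makedirs(args.report, exist_ok=True)
    with open(os.path.join(args.report, "report.json"), "w") as fh:
        fh.write(report.to_json())
    meta = None
    if report.transform is not None:
        meta = {"hankel": report.transform.hankel,
                "T1": report.transform.T1, "S1": report.transform.S1}
    with open(os.path.join(args.report, "reduced_model.json"), "w") as fh:
        fh.write(cr.export_model(report.final_system, "json", metadata=meta))


if __name__ == "__main__":
    main()
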