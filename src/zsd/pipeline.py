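"""Pipeline driver: runs the simulation and analysis stages in order.

The pipeline is configured by a plain mapping (usually loaded from YAML):

.. code-block:: yaml

    stages: [simulate, diversity, richness, compat, mendel, dosage]
    seed: 1
    simulate:
      k: 18
      n_females: 250
      n_males: 250
      generations: 50

Stages run in dependency order (everything downstream consumes the
simulation stage's output), write their tabular outputs under ``out_dir``
and contribute to a combined JSON report. Identical config + seed gives an
identical report (timestamps are deliberately excluded).
"""

from __future__ import annotations

import json
import time
import warnings
from collections import Counter
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import compat, diversity, dosage, io, mendel, richness, simcore
from .errors import InvalidConfigError, ZsdError
from .richness import AlleleCounts, Observation

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "diversity", "richness", "compat", "mendel", "dosage")

REPORT_SCHEMA_VERSION = 1


def _sim_observations(state: simcore.SimState) -> list[Observation]:
    return [
        Observation(
            individual=f"F{i:04d}", population="sim", g1_flag=False, allele_id=f.alleles[0]
        )
        for i, f in enumerate(state.females)
    ]


def run_pipeline(config: dict, out_dir: str | Path = "zsd_out") -> dict:
    """Execute the requested stages and return the combined report dict.

    Raises :class:`InvalidConfigError` for unknown stages; a stage failure
    aborts with the stage named, leaving earlier outputs in place.
    """
    stages = list(config.get("stages", []))
    if not stages:
        warnings.warn("empty stage list: nothing to do", stacklevel=2)
        return {"schema_version": REPORT_SCHEMA_VERSION, "stages": {}}
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise InvalidConfigError(f"unknown stages: {unknown}")
    ordered = [s for s in STAGES if s in stages]
    if ordered != ["simulate"] and "simulate" not in ordered:
        ordered = ["simulate"] + ordered  # downstream stages need simulated data

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": seed, "stages": {}}

    state: simcore.SimState | None = None
    for stage in ordered:
        t0 = time.monotonic()
        io.log(stage=stage, seed=seed, status="start")
        try:
            params = dict(config.get(stage, {}))
            if stage == "simulate":
                cfg = simcore.SimConfig(seed=seed, **params)
                state = simcore.simulate_population(cfg)
                haps = [state.registry[a] for a in sorted(state.final_counts)]
                io.write_haplotypes(out / "haplotypes.fasta", haps)
                io.write_genotype_table(
                    out / "genotypes.tsv", _sim_observations(state)
                )
                report["stages"]["simulate"] = {
                    "extinct": state.extinct,
                    "n_alleles_final": len(state.final_counts),
                    "mean_inviable_fraction": float(
                        np.mean(state.inviable_fraction[1:]) if len(
                            state.inviable_fraction
                        ) > 1 else 0.0
                    ),
                }
            elif stage == "diversity":
                assert state is not None
                haps = [state.registry[a] for a in sorted(state.final_counts)]
                counts = Counter(
                    {a: int(c) for a, c in state.final_counts.items()}
                )
                h_div = diversity.haplotype_diversity(counts)
                hvr_hist = diversity.hvr_length_distribution(haps)
                usage = diversity.codon_usage_profile(haps)
                report["stages"]["diversity"] = {
                    "haplotype_diversity": h_div,
                    "hvr_length_min": min(hvr_hist),
                    "hvr_length_max": max(hvr_hist),
                    "hvr_codons_ant_nat": usage.hvr_ant_nat,
                }
            elif stage == "richness":
                assert state is not None
                counts = AlleleCounts.from_observations(_sim_observations(state))
                spectrum = richness.frequency_spectrum(counts)
                est = richness.ichao1(spectrum)
                report["stages"]["richness"] = {
                    "s_obs": spectrum.s_obs,
                    "n": spectrum.n,
                    "singleton_proportion": spectrum.singleton_proportion,
                    "chao1": est.chao1,
                    "ichao1": est.ichao1,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            elif stage == "compat":
                assert state is not None
                rng = np.random.default_rng(seed + 1)
                observed = [m.alleles for m in state.males]
                counts = Counter(a for pair in observed for a in pair)
                n_males = int(params.get("n_males", 1000))
                simulated = compat.simulate_heterozygous_males(
                    dict(counts), n_males=n_males, rng=rng
                )
                reg = state.registry

                def hvr_edit(pair):
                    return compat.pair_distances(reg[pair[0]], reg[pair[1]]).hvr_edit

                cmp_res = compat.compare_distance_distributions(
                    [hvr_edit(p) for p in observed],
                    [hvr_edit(p) for p in simulated],
                    metric="hvr_edit",
                )
                report["stages"]["compat"] = {
                    "n_observed": len(observed),
                    "n_simulated": len(simulated),
                    "ks_statistic": cmp_res.ks_statistic,
                    "ks_p": cmp_res.p_value,
                }
            elif stage == "mendel":
                assert state is not None
                rng = np.random.default_rng(seed + 2)
                mother, father = state.females[0], state.males[0]
                if mother.alleles[0] not in father.alleles:
                    mother = simcore.Individual("WZ", (father.alleles[0],))
                brood = simcore.simulate_brood(
                    mother, father, int(params.get("n_eggs", 200)), rng
                )
                io.write_brood_table(out / "broods.tsv", [brood])
                expectation = mendel.expected_offspring(mother, father)
                seg = mendel.segregation_chisq(brood.class_counts, expectation)
                report["stages"]["mendel"] = {
                    "inviable_fraction_expected": expectation.inviable_fraction,
                    "black_egg_fraction": brood.black_egg / brood.n_eggs,
                    "segregation_p": seg.p_value,
                    "violations": list(seg.violations),
                }
            elif stage == "dosage":
                rng = np.random.default_rng(seed + 3)
                table = simcore.simulate_expression_matrix(
                    n_auto=int(params.get("n_auto", 2000)),
                    n_z=int(params.get("n_z", 200)),
                    rng=rng,
                )
                io.write_expression_table(out / "expression", table)
                filtered = dosage.filter_expression(table)
                summary = dosage.za_medians(filtered)
                rel = dosage.pairwise_relative_expression(filtered, "hom", "hem")
                report["stages"]["dosage"] = {
                    "za_ratio": summary.za_ratio,
                    "hom_vs_hem_median_z": rel["median_z"],
                    "hom_vs_hem_median_a": rel["median_a"],
                }
        except ZsdError:
            io.log(stage=stage, status="failed")
            raise
        io.log(stage=stage, status="done", wall_s=round(time.monotonic() - t0, 3))

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
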