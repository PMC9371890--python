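"""End-to-end orchestration: simulate -> consensus -> annotate -> spectrum
-> junctions, with per-stage record accounting and a JSON run report.

A single top-level seed deterministically derives per-stage, per-genotype
seeds, so one integer reproduces a whole run bit-for-bit. Rejected records
are never silently dropped: every stage reports input = passed + rejected
and writes its rejection log with reason codes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import __version__, io
from .config import RunConfig
from .errors import ConfigurationError
from .germline import make_germline
from .junctions import (JunctionCohort, compare_insertion_frequencies,
                        compare_mh_distributions, insertion_frequency,
                        relative_csr_efficiency, score_cohort)
from .spectrum import SpectrumConfig, aggregate, compare_genotypes
from .synthetic_data import (PROFILES, JunctionMixture, make_switch_references,
                             simulate_csr_counts, simulate_junctions, simulate_reads,
                             simulate_repertoire)
from .umi_consensus import process_read_pairs
from .annotation import annotate_all

log = logging.getLogger("shmcsr")

#: Junction mixtures emulating the qualitative genotype contrast: the
#: wild-type-like group is microhomology-rich, the nuclease-dead-like group
#: shifts toward blunt joins and untemplated insertions, the knockout-like
#: group loses long microhomologies without the insertion excess.
JUNCTION_MIXTURES: dict[str, JunctionMixture] = {
    "WT-like": JunctionMixture(p_blunt=0.20, p_mh=0.72, p_ins=0.08),
    "DA-like": JunctionMixture(p_blunt=0.36, p_mh=0.38, p_ins=0.26,
                               mh_length_dist={1: 0.45, 2: 0.30, 3: 0.15, 4: 0.10},
                               ins_length_dist={1: 0.35, 2: 0.30, 3: 0.20, 4: 0.15}),
    "KO-like": JunctionMixture(p_blunt=0.30, p_mh=0.60, p_ins=0.10,
                               mh_length_dist={1: 0.40, 2: 0.28, 3: 0.18, 4: 0.14}),
}

#: Per-animal class-switch probabilities and cohort sizes (animals) used by
#: the simulated CSR readout; mutant cohorts switch at roughly half the
#: wild-type-like rate.
CSR_SETTINGS: dict[str, tuple[float, int]] = {
    "WT-like": (0.25, 8),
    "DA-like": (0.10, 8),
    "KO-like": (0.12, 5),
}


def _stage_seeds(seed: int, n: int = 16) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2 ** 31)) for s in state]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and return the run report dict."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 8 + 8 * len(config.genotypes))
    report: dict = {"seed": config.seed, "version": __version__, "stages": {},
                    "stage_order": list(config.stages), "genotypes": list(config.genotypes)}

    germline = make_germline(config.germline_length, config.gc_fraction, seed=seeds[0])

    if "simulate" in config.stages:
        report["stages"]["simulate"] = _stage_simulate(config, germline, out, seeds)
    if "consensus" in config.stages:
        report["stages"]["consensus"] = _stage_consensus(config, out)
    if "annotate" in config.stages:
        report["stages"]["annotate"] = _stage_annotate(config, out)
    if "spectrum" in config.stages:
        report["stages"]["spectrum"] = _stage_spectrum(config, out, seeds)
    if "junctions" in config.stages:
        report["stages"]["junctions"] = _stage_junctions(config, out, seeds)

    for name, rec in report["stages"].items():
        if rec.get("input", 0) != rec.get("passed", 0) + rec.get("rejected", 0):
            raise ConfigurationError(f"stage {name} record accounting broken")
    io.write_json(out / "run_report.json", report)
    return report


def _geometric(p):
    return lambda rng: int(rng.geometric(p))


def _stage_simulate(config: RunConfig, germline, out: Path, seeds) -> dict:
    io.write_germline(out / "germline.fasta", out / "germline_regions.tsv", germline)
    n_mols = 0
    for gi, geno in enumerate(config.genotypes):
        profile = PROFILES[geno]
        mols, truth = simulate_repertoire(
            germline, profile, n_clones=config.n_clones,
            clone_size_dist=_geometric(config.clone_size_geometric_p),
            inherited_fraction=config.inherited_fraction, seed=seeds[8 + 8 * gi])
        pairs, umi_of = simulate_reads(
            mols, umi_length=config.umi_length, reads_per_molecule=config.reads_per_molecule,
            error_rate=config.error_rate, overlap=config.overlap, seed=seeds[8 + 8 * gi + 1])
        truth.umi_of = umi_of
        io.write_fastq_pairs(out / f"{geno}_R1.fastq", out / f"{geno}_R2.fastq", pairs)
        io.write_fasta(out / f"{geno}_molecules.fasta", [(m.id, m.sequence) for m in mols])
        _write_truth(out / f"{geno}_truth.tsv", mols, truth)
        n_mols += len(mols)
        log.info("simulated %s: %d molecules, %d read pairs", geno, len(mols), len(pairs))
    return {"input": n_mols, "passed": n_mols, "rejected": 0}


def _write_truth(path, mols, truth) -> None:
    import pandas as pd

    rows = []
    for m in mols:
        for mut in truth.mutations[m.id]:
            rows.append({"molecule": m.id, "clone": truth.clone_of[m.id],
                         "umi": truth.umi_of.get(m.id, ""), "position": mut.position + 1,
                         "from_base": mut.from_base, "to_base": mut.to_base,
                         "inherited": mut.inherited})
    pd.DataFrame(rows, columns=["molecule", "clone", "umi", "position", "from_base",
                                "to_base", "inherited"]).to_csv(path, sep="\t", index=False)


def _stage_consensus(config: RunConfig, out: Path) -> dict:
    total_in = passed = rejected = 0
    for geno in config.genotypes:
        pairs = io.read_fastq_pairs(out / f"{geno}_R1.fastq", out / f"{geno}_R2.fastq")
        consensuses, rejects = process_read_pairs(
            pairs, umi_length=config.umi_length, min_overlap=config.min_overlap,
            max_mismatch_frac=config.merge_max_mismatch_frac,
            min_family_size=config.min_family_size)
        io.write_consensus_fasta(out / f"{geno}_consensus.fasta", consensuses)
        io.write_rejects(out / f"{geno}_consensus_rejects.tsv", rejects)
        total_in += len(pairs)
        rejected += len(rejects)
        passed += len(pairs) - len(rejects)
    return {"input": total_in, "passed": passed, "rejected": rejected}


def _stage_annotate(config: RunConfig, out: Path) -> dict:
    germline = io.read_germline(out / "germline.fasta", out / "germline_regions.tsv")
    total_in = passed = rejected = 0
    for geno in config.genotypes:
        consensuses = io.read_consensus_fasta(out / f"{geno}_consensus.fasta")
        annotated, rejects = annotate_all(consensuses, germline,
                                          max_mismatch_frac=config.annotate_max_mismatch_frac)
        io.write_annotation(out / f"{geno}_annotation.tsv", annotated)
        io.write_clone_table(out / f"{geno}_clones.tsv", annotated)
        io.write_rejects(out / f"{geno}_annotation_rejects.tsv", rejects)
        total_in += len(consensuses)
        passed += len(annotated)
        rejected += len(rejects)
    return {"input": total_in, "passed": passed, "rejected": rejected}


def _stage_spectrum(config: RunConfig, out: Path, seeds) -> dict:
    germline = io.read_germline(out / "germline.fasta", out / "germline_regions.tsv")
    results = {}
    n_in = 0
    for gi, geno in enumerate(config.genotypes):
        annotated = io.read_annotated(out / f"{geno}_annotation.tsv", out / f"{geno}_clones.tsv")
        n_in += len(annotated)
        cfg = SpectrumConfig(n_iterations=config.n_iterations, seed=seeds[8 + 8 * gi + 2],
                             alpha=config.alpha)
        res = aggregate(annotated, germline, cfg)
        results[geno] = res
        res.spectrum_frame().to_csv(out / f"{geno}_spectrum.tsv", sep="\t", index=False)
        res.positional_profile.to_csv(out / f"{geno}_positional_profile.tsv",
                                      sep="\t", index=False)
    contrasts = []
    ref = config.genotypes[0]
    for geno in config.genotypes[1:]:
        frame = compare_genotypes(results[ref], results[geno])
        frame.insert(0, "comparison", f"{ref}_vs_{geno}")
        contrasts.append(frame)
    if contrasts:
        import pandas as pd

        pd.concat(contrasts, ignore_index=True).to_csv(out / "spectrum_contrasts.tsv",
                                                       sep="\t", index=False)
    io.write_json(out / "spectrum_summary.json", {
        "seed": config.seed, "version": __version__, "n_iterations": config.n_iterations,
        "mean_frequencies": {g: results[g].mean for g in results},
        "eligible_sites": results[ref].site_counts})
    return {"input": n_in, "passed": n_in, "rejected": 0}


def _stage_junctions(config: RunConfig, out: Path, seeds) -> dict:
    donor, acceptor = make_switch_references(config.switch_ref_length, config.switch_ref_length,
                                             seed=seeds[1])
    io.write_fasta(out / "switch_references.fasta", [("Smu_donor", donor),
                                                     ("Sgamma3_acceptor", acceptor)])
    cohorts: list[JunctionCohort] = []
    truth_rows = []
    n_in = rejected = 0
    for gi, geno in enumerate(config.genotypes):
        mixture = JUNCTION_MIXTURES[geno]
        sims = simulate_junctions(donor, acceptor, mixture, config.n_junctions,
                                  seed=seeds[8 + 8 * gi + 3], anchor_min=config.anchor_min)
        io.write_fasta(out / f"{geno}_junctions.fasta",
                       [(s.id, s.sequence) for s in sims])
        cohort = score_cohort(geno, [(s.id, s.sequence) for s in sims], donor, acceptor,
                              anchor_min=config.anchor_min)
        cohorts.append(cohort)
        truth_rows.extend({"genotype": geno, "id": s.id, "truth_label": s.label} for s in sims)
        n_in += len(sims)
        rejected += sum(1 for j in cohort.junctions if not j.resolved)

    io.write_junction_table(out / "junction_scores.tsv", cohorts)
    import pandas as pd

    pd.DataFrame(truth_rows).to_csv(out / "junction_truth.tsv", sep="\t", index=False)

    kw = compare_mh_distributions(cohorts, method="asymptotic")
    stats_payload: dict = {
        "kruskal_wallis": {"H": kw["H"], "p": kw["p"], "method": kw["method"]},
        "dunn": kw["dunn"].to_dict(orient="records"),
        "insertion_frequency": {c.genotype: insertion_frequency(c) for c in cohorts},
        "fisher_insertions": {},
        "csr_relative_efficiency": {},
    }
    ref = cohorts[0]
    for c in cohorts[1:]:
        p, oratio = compare_insertion_frequencies(ref, c)
        stats_payload["fisher_insertions"][f"{ref.genotype}_vs_{c.genotype}"] = {
            "p": p, "odds_ratio": oratio}

    csr_fracs = {}
    for gi, geno in enumerate(config.genotypes):
        p_switch, n_animals = CSR_SETTINGS[geno]
        csr_fracs[geno] = simulate_csr_counts(p_switch, config.csr_n_cells, n_animals,
                                              seed=seeds[8 + 8 * gi + 4])
    ref_geno = config.genotypes[0]
    for geno in config.genotypes:
        rel = relative_csr_efficiency(csr_fracs[geno], csr_fracs[ref_geno])
        stats_payload["csr_relative_efficiency"][geno] = [round(float(x), 4) for x in rel]

    io.write_json(out / "junction_stats.json", stats_payload)
    return {"input": n_in, "passed": n_in - rejected, "rejected": rejected}
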