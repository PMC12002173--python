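"""End-to-end orchestration: simulate -> reconstruct -> classify -> report.

A :class:`RunConfig` names the stages to run and their parameters; all
randomness flows from the single config seed, fanned out to per-stage
substreams by a fixed derivation, so one number reproduces a whole run.
Every run writes the fully resolved config and a machine-readable report
next to its outputs.  Results go to files; logging goes to stderr.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .active_site import (
    CatalyticSiteModel,
    activity_character,
    call_active_site,
    load_default_model,
)
from .biochem import alkylation_accessibility, endpoint_rate, fit_calibration, oa_attribution
from .burden import MutationCatalog, gene_burden
from .datasets import gnathostome_matrix
from .dollo import BinaryCharacterMatrix, event_table, map_characters
from .errors import InvalidArgumentError, NotFoundError
from .io import read_msa_fasta, write_msa_fasta
from .phylo import read_newick
from .phyloprofile import rank_coevolving
from .simulate import (
    GeneSpec,
    sim_alkylation_table,
    sim_assay,
    sim_catalytic_msa,
    sim_mutation_catalog,
    sim_profile_matrix,
    sim_tree,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("pseudolock")

STAGES = ("sim", "dollo", "sites", "profile", "burden", "assay", "alkyl")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``stages`` maps stage name -> parameter block; a stage runs iff its
    block is present and ``enabled`` is not false.  Unknown top-level
    keys, unknown stage names and unknown stage parameters are rejected.
    """

    seed: int = 0
    out_dir: str = "pseudolock_run"
    stages: dict[str, dict] = field(default_factory=dict)

    _STAGE_KEYS: dict[str, set[str]] = field(
        default_factory=lambda: {
            "sim": {
                "enabled", "n_tips", "n_genes", "n_coevolving", "flip_noise",
                "loss_rate", "pseudo_clade", "n_samples", "n_buried",
                "n_exposed", "separation", "true_rates", "calib_slope",
                "calib_intercept", "contaminant_rate", "oa_inhibits_contaminant",
                "noise_sd",
            },
            "dollo": {"enabled", "tree", "states"},
            "sites": {"enabled", "msa", "model"},
            "profile": {"enabled", "tree", "matrix", "query", "n_perm"},
            "burden": {"enabled", "catalog", "lengths", "cnv", "alpha"},
            "assay": {"enabled", "standards", "endpoints", "incubation_time_min",
                      "enzyme_conc", "inhibitor_conc"},
            "alkyl": {"enabled", "table", "pseudocount"},
        },
        repr=False,
    )

    def __post_init__(self) -> None:
        for name, block in self.stages.items():
            if name not in STAGES:
                raise InvalidArgumentError(f"unknown stage {name!r}")
            unknown = set(block) - self._STAGE_KEYS[name]
            if unknown:
                raise InvalidArgumentError(
                    f"unknown keys in stage {name!r}: {sorted(unknown)}"
                )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise InvalidArgumentError("config must be a mapping")
        unknown = set(data) - {"seed", "out_dir", "stages"}
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            seed=int(data.get("seed", 0)),
            out_dir=str(data.get("out_dir", "pseudolock_run")),
            stages=dict(data.get("stages", {})),
        )

    def resolved(self) -> dict:
        return {"seed": self.seed, "out_dir": self.out_dir, "stages": self.stages}


def _stage_seed(seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


def _resolve(path_or_tag: str, out: Path, produced: dict[str, Path]) -> Path:
    """Resolve a stage input: a literal path, or ``sim:<name>`` for a file
    produced by the sim stage of this run."""
    if path_or_tag.startswith("sim:"):
        key = path_or_tag[4:]
        if key not in produced:
            raise NotFoundError(f"sim stage did not produce {key!r}")
        return produced[key]
    p = Path(path_or_tag)
    if not p.exists():
        raise NotFoundError(f"input file not found: {p}")
    return p


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order; return the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.resolved.json").write_text(json.dumps(config.resolved(), indent=1))

    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "ok": True,
    }
    produced: dict[str, Path] = {}

    for stage in STAGES:
        block = config.stages.get(stage)
        if block is None or block.get("enabled", True) is False:
            report["stages"][stage] = {"status": "skipped"}
            continue
        log.info("running stage %s", stage)
        entry: dict[str, Any] = {"status": "ok", "outputs": [], "warnings": []}
        try:
            runner = globals()[f"_run_{stage}"]
            runner(block, config, out, produced, entry)
        except Exception as exc:  # report partial results, fail the run
            log.error("stage %s failed: %s", stage, exc)
            entry["status"] = "error"
            entry["error"] = str(exc)
            report["ok"] = False
        entry["outputs"] = [str(p) for p in entry.get("outputs", [])]
        report["stages"][stage] = entry

    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


# --- stage runners ---------------------------------------------------------

def _run_sim(block: Mapping, config: RunConfig, out: Path, produced, entry) -> None:
    seed = _stage_seed(config.seed, "sim")
    ss = np.random.SeedSequence(seed)
    subseeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    simdir = out / "sim"
    simdir.mkdir(exist_ok=True)

    tree = sim_tree(int(block.get("n_tips", 30)), subseeds[0])
    (simdir / "tree.nwk").write_text(tree.to_newick() + "\n")
    produced["tree"] = simdir / "tree.nwk"

    matrix, truth = sim_profile_matrix(
        tree,
        int(block.get("n_genes", 50)),
        int(block.get("n_coevolving", 3)),
        float(block.get("flip_noise", 0.02)),
        subseeds[1],
        loss_rate=float(block.get("loss_rate", 0.1)),
    )
    matrix.to_tsv(simdir / "profile_matrix.tsv")
    truth.to_json(simdir / "profile_truth.json")
    produced["matrix"] = simdir / "profile_matrix.tsv"

    model = load_default_model()
    pseudo_clade = block.get("pseudo_clade") or tree.children(tree.root)[0]
    aln, msa_truth = sim_catalytic_msa(tree, model, pseudo_clade, subseeds[2])
    write_msa_fasta(aln, simdir / "msa.fasta")
    msa_truth.to_json(simdir / "msa_truth.json")
    with open(simdir / "site_model.json", "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
    produced["msa"] = simdir / "msa.fasta"
    produced["site_model"] = simdir / "site_model.json"

    specs = [
        GeneSpec.tsg("TSG1"), GeneSpec.tsg("TSG2"),
        GeneSpec.oncogene("ONC1"), GeneSpec.oncogene("ONC2"),
        GeneSpec.neutral("OR_A"), GeneSpec.neutral("OR_B"),
        GeneSpec.neutral("PHLPP_like1", length_aa=1200),
        GeneSpec.neutral("PHLPP_like2", length_aa=1400),
    ]
    catalog, cnv_tables, mut_truth = sim_mutation_catalog(
        specs, int(block.get("n_samples", 200)), subseeds[3]
    )
    catalog.records.to_csv(simdir / "mutations.tsv", sep="\t", index=False)
    pd.Series(catalog.gene_lengths, name="length_aa").rename_axis("gene").to_csv(
        simdir / "lengths.tsv", sep="\t"
    )
    pd.concat(
        [t.assign(gene=g) for g, t in cnv_tables.items()], ignore_index=True
    ).to_csv(simdir / "cnv.tsv", sep="\t", index=False)
    mut_truth.to_json(simdir / "mutation_truth.json")
    produced["catalog"] = simdir / "mutations.tsv"
    produced["lengths"] = simdir / "lengths.tsv"
    produced["cnv"] = simdir / "cnv.tsv"

    table, alk_truth = sim_alkylation_table(
        int(block.get("n_buried", 2)),
        int(block.get("n_exposed", 3)),
        float(block.get("separation", 6.0)),
        subseeds[4],
    )
    table.to_csv(simdir / "alkylation.tsv", sep="\t", index=False)
    alk_truth.to_json(simdir / "alkylation_truth.json")
    produced["alkyl_table"] = simdir / "alkylation.tsv"

    sim = sim_assay(
        list(block.get("true_rates", [0.0, 2e-11])),
        float(block.get("calib_slope", 5e8)),
        float(block.get("calib_intercept", 0.01)),
        float(block.get("contaminant_rate", 1e-11)),
        bool(block.get("oa_inhibits_contaminant", True)),
        float(block.get("noise_sd", 0.002)),
        subseeds[5],
    )
    sim.standards.to_csv(simdir / "assay_standards.tsv", sep="\t", index=False)
    sim.endpoints.to_csv(simdir / "assay_endpoints.tsv", sep="\t", index=False)
    pd.DataFrame({"blank": sim.blanks}).to_csv(simdir / "assay_blanks.tsv", sep="\t", index=False)
    sim.truth.to_json(simdir / "assay_truth.json")
    produced["standards"] = simdir / "assay_standards.tsv"
    produced["endpoints"] = simdir / "assay_endpoints.tsv"
    produced["blanks"] = simdir / "assay_blanks.tsv"

    entry["outputs"] = sorted(simdir.iterdir())


def _load_tree_and_states(block, out, produced):
    tree_src = block.get("tree", "sim:tree")
    states_src = block.get("states", "sim:matrix")
    if tree_src == "builtin:gnathostome_phlpp2" or states_src == "builtin:gnathostome_phlpp2":
        return gnathostome_matrix()
    tree = read_newick(_resolve(tree_src, out, produced).read_text())
    matrix = BinaryCharacterMatrix.read_tsv(_resolve(states_src, out, produced))
    return tree, matrix


def _run_dollo(block, config, out, produced, entry) -> None:
    tree, matrix = _load_tree_and_states(block, out, produced)
    recons, annotated = map_characters(tree, matrix)
    events = event_table(recons)
    events.to_csv(out / "dollo_events.tsv", sep="\t", index=False)
    (out / "dollo_annotated.nwk").write_text(annotated + "\n")
    entry["outputs"] = [out / "dollo_events.tsv", out / "dollo_annotated.nwk"]
    entry["loss_counts"] = {
        r.character: r.n_losses for r in recons
    }


def _run_sites(block, config, out, produced, entry) -> None:
    msa = read_msa_fasta(_resolve(block.get("msa", "sim:msa"), out, produced))
    model_src = block.get("model", "sim:site_model")
    if model_src == "builtin:ppm1a":
        model = load_default_model()
    else:
        model = CatalyticSiteModel.from_json(_resolve(model_src, out, produced))
    calls = call_active_site(msa, model)
    rows = [
        dict(
            sequence=c.sequence_id,
            classification=c.classification,
            m2_zinc_flag=c.m2_zinc_flag,
            residues=";".join(f"{r[0]}:{r[1]}{r[2]}" for r in c.residues),
        )
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(out / "site_calls.tsv", sep="\t", index=False)
    char = activity_character([c for c in calls if c.sequence_id != model.reference_id])
    pd.Series(
        {k: ("?" if v is None else v) for k, v in char.items()}, name="active_site"
    ).rename_axis("taxon").to_csv(out / "activity_character.tsv", sep="\t")
    entry["outputs"] = [out / "site_calls.tsv", out / "activity_character.tsv"]


def _run_profile(block, config, out, produced, entry) -> None:
    tree, matrix = _load_tree_and_states(
        {"tree": block.get("tree", "sim:tree"), "states": block.get("matrix", "sim:matrix")},
        out, produced,
    )
    ranking = rank_coevolving(
        tree,
        matrix,
        block.get("query", "query"),
        n_perm=int(block.get("n_perm", 199)),
        seed=_stage_seed(config.seed, "profile"),
    )
    ranking.to_csv(out / "profile_ranking.tsv", sep="\t", index=False)
    entry["outputs"] = [out / "profile_ranking.tsv"]


def _run_burden(block, config, out, produced, entry) -> None:
    catalog = MutationCatalog.read_tsv(
        _resolve(block.get("catalog", "sim:catalog"), out, produced),
        _resolve(block.get("lengths", "sim:lengths"), out, produced),
    )
    cnv_long = pd.read_csv(_resolve(block.get("cnv", "sim:cnv"), out, produced), sep="\t")
    cnv_tables = {g: t[["sample", "call"]] for g, t in cnv_long.groupby("gene")}
    burdens = gene_burden(catalog, cnv_tables, alpha=float(block.get("alpha", 0.05)))
    rows = [
        dict(
            gene=b.gene, syn_rate=b.syn_rate, nonsyn_rate=b.nonsyn_rate,
            truncating_fraction=b.truncating_fraction,
            hotspots=";".join(str(h.codon) for h in b.hotspots),
            cnl_freq=b.cnl_freq, cng_freq=b.cng_freq, skew=b.skew,
            classification=b.classification, conflict=b.conflict,
        )
        for b in burdens
    ]
    pd.DataFrame(rows).to_csv(out / "gene_burden.tsv", sep="\t", index=False)
    entry["outputs"] = [out / "gene_burden.tsv"]


def _run_assay(block, config, out, produced, entry) -> None:
    standards = pd.read_csv(
        _resolve(block.get("standards", "sim:standards"), out, produced), sep="\t"
    )
    endpoints = pd.read_csv(
        _resolve(block.get("endpoints", "sim:endpoints"), out, produced), sep="\t"
    )
    blanks_path = produced.get("blanks")
    blanks = (
        pd.read_csv(blanks_path, sep="\t")["blank"].to_numpy()
        if blanks_path is not None
        else np.zeros(3)
    )
    calib = fit_calibration(
        list(zip(standards["phosphate_mol"], standards["absorbance"]))
    )
    t_inc = float(block.get("incubation_time_min", 60.0))
    rows = []
    for idx, grp in endpoints.groupby("rate_index"):
        by_cond = grp.set_index("condition")["absorbance"]
        r_un, det = endpoint_rate(float(by_cond["untreated"]), blanks, calib, t_inc)
        r_tr, _ = endpoint_rate(float(by_cond["inhibitor"]), blanks, calib, t_inc)
        verdict, f = oa_attribution(
            r_un, r_tr,
            float(block.get("enzyme_conc", 100e-9)),
            float(block.get("inhibitor_conc", 12.5e-9)),
            untreated_detectable=det,
        )
        rows.append(
            dict(rate_index=idx, rate_untreated=r_un, rate_inhibitor=r_tr,
                 detectable=det, inhibited_fraction=f, verdict=verdict)
        )
    pd.DataFrame(rows).to_csv(out / "assay_report.tsv", sep="\t", index=False)
    entry["outputs"] = [out / "assay_report.tsv"]


def _run_alkyl(block, config, out, produced, entry) -> None:
    table = pd.read_csv(
        _resolve(block.get("table", "sim:alkyl_table"), out, produced), sep="\t"
    )
    calls = alkylation_accessibility(table, pseudocount=float(block.get("pseudocount", 1.0)))
    calls.to_csv(out / "alkylation_calls.tsv", sep="\t", index=False)
    entry["outputs"] = [out / "alkylation_calls.tsv"]
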