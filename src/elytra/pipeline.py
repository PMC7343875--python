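"""Staged pipeline binding simulation, measurement, classification,
OTU delimitation and phylogenetics into a reproducible run directory.

Each stage writes its outputs plus a manifest entry (inputs, parameters,
seed, package versions, output hashes); a rerun with an identical
configuration is byte-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as eio
from .classifier import ClassifierConfig, classify_all, community_summary, dimorphism_scan
from .color import contrast_profile, costa_cell_contrast, sample_region
from .morphometrics import count_transverse, measure_cells
from .otu import (
    DEFAULT_THRESHOLD,
    assign_representatives,
    build_distance_matrix,
    cluster_otus,
)
from .phylo import (
    PAPER_RATE_TABLE,
    PatternTree,
    RateTable,
    min_origins,
    node_ages,
    time_scale,
)
from .simulate import (
    ClockSimSpec,
    ElytronSpec,
    SeqSimSpec,
    gen_clock_tree,
    gen_community,
    gen_elytron,
    gen_sequences,
)

STAGES = ("simulate", "colour", "classify", "otu", "phylo", "report")


class StageError(RuntimeError):
    """A stage prerequisite is missing or a stage name is unknown."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    outdir: Path
    seed: int = 0
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    otu_threshold: float = DEFAULT_THRESHOLD
    rates: "RateTable" = PAPER_RATE_TABLE
    focal_pattern: str = "C"
    n_focal_origins: int = 4
    clock_leaves: int = 20

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "classifier": dataclasses.asdict(self.classifier),
            "otu_threshold": self.otu_threshold,
            "rates": dict(PAPER_RATE_TABLE.rates),
            "focal_pattern": self.focal_pattern,
            "n_focal_origins": self.n_focal_origins,
            "clock_leaves": self.clock_leaves,
        }


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, stages: Sequence[str]) -> Path:
    """Run the requested stages in canonical order; returns the run directory."""
    for st in stages:
        if st not in STAGES:
            raise StageError(f"unknown stage {st!r}; choose from {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest.setdefault("config", config.as_dict())
    manifest.setdefault("stages", {})
    ordered = [st for st in STAGES if st in stages]
    for st in ordered:
        outputs = _STAGE_FUNCS[st](config, outdir)
        manifest["stages"][st] = {
            "outputs": {str(p.relative_to(outdir)): _sha(p) for p in outputs},
            "seed": config.seed,
        }
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return outdir


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StageError(
            f"missing prerequisite {path.name!r}: run the {producer!r} stage first"
        )
    return path


def _stage_simulate(config: RunConfig, outdir: Path) -> list[Path]:
    sim = outdir / "simulated"
    sim.mkdir(exist_ok=True)
    outputs = []
    # elytron images, one per pattern
    for i, pattern in enumerate(("A", "B", "C", "BLACK")):
        spec = ElytronSpec.for_pattern(pattern, seed=config.seed + i)
        syn = gen_elytron(spec)
        img = sim / f"elytron_{pattern}.png"
        eio.write_image(syn.image, img)
        eio.write_mask(syn.costa_mask, sim / f"elytron_{pattern}_costa_mask.png")
        eio.write_mask(syn.cell_mask, sim / f"elytron_{pattern}_cell_mask.png")
        ann = sim / f"elytron_{pattern}.json"
        eio.write_annotation(
            {
                "region_polygons": syn.region_polygons,
                "costa_points": syn.costa_points,
                "cell_points": syn.cell_points,
                "transect": syn.transect,
                "truth": syn.truth,
            },
            ann,
        )
        outputs += [img, ann]
    # community
    records, truth = gen_community(seed=config.seed)
    spec_path = sim / "specimens.tsv"
    eio.write_specimen_table(records, spec_path, seed=config.seed)
    truth_path = sim / "community_truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(eio.output_header(config.seed) + "\n")
        truth.to_csv(fh, sep="\t", index=False)
    outputs += [spec_path, truth_path]
    # sequences
    seqs_by_gene, otu_truth = gen_sequences(SeqSimSpec(seed=config.seed))
    for gene, seqs in seqs_by_gene.items():
        p = sim / f"align_{gene}.fasta"
        eio.write_fasta(seqs, p)
        outputs.append(p)
    with open(sim / "otu_truth.tsv", "w") as fh:
        fh.write(eio.output_header(config.seed) + "\n")
        fh.write("seq_id\totu_id\n")
        for sid in sorted(otu_truth):
            fh.write(f"{sid}\t{otu_truth[sid]}\n")
    outputs.append(sim / "otu_truth.tsv")
    # clock tree with focal states
    csim = gen_clock_tree(
        ClockSimSpec(
            n_leaves=config.clock_leaves,
            n_focal_origins=config.n_focal_origins,
            focal_state=config.focal_pattern,
            poisson_noise=True,
            seed=config.seed,
        )
    )
    tree_dir = sim
    for gene in csim.spec.rates.rates:
        t = csim.pattern_tree.tree.clone(depth=1)
        for node_src, node_out in zip(
            csim.pattern_tree.tree.preorder_node_iter(), t.preorder_node_iter()
        ):
            node_out.edge.length = (
                None
                if node_src.parent_node is None
                else node_src.partition_lengths[gene]
            )
        p = tree_dir / f"tree_{gene}.nwk"
        p.write_text(t.as_string(schema="newick", suppress_rooting=True))
        outputs.append(p)
    with open(sim / "leaf_states.tsv", "w") as fh:
        fh.write(eio.output_header(config.seed) + "\n")
        fh.write("leaf\tpattern\n")
        for leaf, st in sorted(csim.pattern_tree.leaf_states.items()):
            fh.write(f"{leaf}\t{st}\n")
    outputs.append(sim / "leaf_states.tsv")
    return outputs


def _stage_colour(config: RunConfig, outdir: Path) -> list[Path]:
    sim = outdir / "simulated"
    rows = []
    profiles = []
    for pattern in ("A", "B", "C", "BLACK"):
        img_p = _require(sim / f"elytron_{pattern}.png", "simulate")
        ann = eio.read_annotation(sim / f"elytron_{pattern}.json")
        image = eio.read_image(img_p)
        samples = {}
        for region, poly in ann["region_polygons"].items():
            rs = sample_region(
                image, poly, seed=config.seed, region_label=region
            )
            samples[region] = rs
            rows.append(
                {
                    "specimen": f"elytron_{pattern}",
                    "region": region,
                    "L": rs.mean_lab.L,
                    "a": rs.mean_lab.a,
                    "b": rs.mean_lab.b,
                    "n_patches": rs.n_patches,
                }
            )
        d_cc = costa_cell_contrast(
            image, ann["costa_points"], ann["cell_points"], seed=config.seed
        )
        prof = contrast_profile(samples)
        profiles.append(
            {
                "specimen": f"elytron_{pattern}",
                "delta_humeral_apical": prof.delta_humeral_apical,
                "delta_humeral_middle": prof.delta_humeral_middle,
                "delta_costa_cell": d_cc,
            }
        )
    import pandas as pd

    out1 = outdir / "region_means.tsv"
    out2 = outdir / "contrast_profiles.tsv"
    for path, data in ((out1, rows), (out2, profiles)):
        with open(path, "w") as fh:
            fh.write(eio.output_header(config.seed, config.as_dict()) + "\n")
            pd.DataFrame(data).to_csv(fh, sep="\t", index=False)
    return [out1, out2]


def _stage_classify(config: RunConfig, outdir: Path) -> list[Path]:
    spec_path = _require(outdir / "simulated" / "specimens.tsv", "simulate")
    records = eio.read_specimen_table(spec_path)
    classified = classify_all(records, config.classifier)
    out = outdir / "classified.tsv"
    eio.write_specimen_table(
        classified, out, seed=config.seed, config=config.as_dict()
    )
    summary = community_summary(classified)
    summary_sp = community_summary(classified, by="species")
    dim = dimorphism_scan(classified)
    out2 = outdir / "community_summary.tsv"
    with open(out2, "w") as fh:
        fh.write(eio.output_header(config.seed, config.as_dict()) + "\n")
        summary.assign(by="individuals").to_csv(fh, sep="\t", index=False)
        summary_sp.assign(by="species").to_csv(fh, sep="\t", index=False, header=False)
    out3 = outdir / "dimorphism.json"
    out3.write_text(json.dumps(dim, indent=1) + "\n")
    return [out, out2, out3]


def _stage_otu(config: RunConfig, outdir: Path) -> list[Path]:
    sim = outdir / "simulated"
    fastas = sorted(sim.glob("align_*.fasta"))
    if not fastas:
        raise StageError("missing prerequisite alignments: run 'simulate' first")
    seqs_by_gene = {
        p.stem.removeprefix("align_"): eio.read_fasta(p, p.stem.removeprefix("align_"))
        for p in fastas
    }
    m = build_distance_matrix(seqs_by_gene)
    partition = cluster_otus(m, threshold=config.otu_threshold)
    all_seqs = [s for seqs in seqs_by_gene.values() for s in seqs]
    partition = assign_representatives(partition, all_seqs)
    out1 = outdir / "distances.tsv"
    eio.write_distance_long(m, out1, seed=config.seed)
    out2 = outdir / "otus.tsv"
    eio.write_otu_table(partition, out2, seed=config.seed)
    reps = set((partition.representatives or {}).values())
    out3 = outdir / "pruned.fasta"
    gene0 = sorted(seqs_by_gene)[0]
    eio.write_fasta(
        [s for s in seqs_by_gene[gene0] if s.seq_id in reps], out3
    )
    return [out1, out2, out3]


def _stage_phylo(config: RunConfig, outdir: Path) -> list[Path]:
    sim = outdir / "simulated"
    newicks = {
        p.stem.removeprefix("tree_"): eio.read_newick_text(p)
        for p in sorted(sim.glob("tree_*.nwk"))
    }
    if not newicks:
        raise StageError("missing prerequisite trees: run 'simulate' first")
    states_path = _require(sim / "leaf_states.tsv", "simulate")
    import pandas as pd

    states_df = pd.read_csv(states_path, sep="\t", comment="#")
    leaf_states = dict(zip(states_df["leaf"], states_df["pattern"]))
    ptree = PatternTree.from_newicks(newicks, leaf_states)
    report = min_origins(ptree, config.focal_pattern)
    ttree = time_scale(ptree, PAPER_RATE_TABLE)
    ages = node_ages(ttree)
    out1 = outdir / "origins.json"
    out1.write_text(json.dumps(dataclasses.asdict(report), indent=1) + "\n")
    out2 = outdir / "time_tree.nwk"
    out2.write_text(ttree.as_string(schema="newick", suppress_rooting=True))
    out3 = outdir / "node_ages.tsv"
    with open(out3, "w") as fh:
        fh.write(eio.output_header(config.seed) + "\n")
        fh.write("node_leaves\tage_my\n")
        for node, age in ages.items():
            if not node.is_leaf():
                key = ",".join(sorted(lf.taxon.label for lf in node.leaf_iter()))
                fh.write(f"{key}\t{age:.6f}\n")
    return [out1, out2, out3]


def _stage_report(config: RunConfig, outdir: Path) -> list[Path]:
    import pandas as pd

    report: dict = {"seed": config.seed}
    truth_path = _require(outdir / "simulated" / "community_truth.tsv", "simulate")
    truth = pd.read_csv(truth_path, sep="\t", comment="#")
    classified_path = _require(outdir / "classified.tsv", "classify")
    classified = pd.read_csv(classified_path, sep="\t", comment="#")
    merged = truth.merge(
        classified[["specimen_id", "pattern"]], on="specimen_id", suffixes=("_true", "_assigned")
    )
    report["classification_accuracy"] = float(
        (merged["pattern_true"] == merged["pattern_assigned"]).mean()
    )
    otu_truth = pd.read_csv(
        outdir / "simulated" / "otu_truth.tsv", sep="\t", comment="#"
    )
    otus = pd.read_csv(_require(outdir / "otus.tsv", "otu"), sep="\t", comment="#")
    m = otu_truth.merge(otus, on="seq_id")
    # exact partition recovery: true and inferred labels must be bijective
    pairs = m.groupby(["otu_id_x", "otu_id_y"]).size()
    report["otu_partition_exact"] = bool(
        len(pairs) == m["otu_id_x"].nunique() == m["otu_id_y"].nunique()
    )
    report["n_otus_inferred"] = int(m["otu_id_y"].nunique())
    origins = json.loads(_require(outdir / "origins.json", "phylo").read_text())
    report["min_origins"] = origins["min_origins"]
    report["terminal_only"] = origins["terminal_only"]
    out = outdir / "report.json"
    out.write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return [out]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "colour": _stage_colour,
    "classify": _stage_classify,
    "otu": _stage_otu,
    "phylo": _stage_phylo,
    "report": _stage_report,
}
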