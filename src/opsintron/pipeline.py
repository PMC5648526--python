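"""End-to-end orchestration: screen, prune, map, conserve, compare, report.

The pipeline runs the analysis stages in their scientific order —
diagnostic screening of candidates, leaf-stability pruning of rogue taxa
against a bootstrap tree set, projection of intron marks onto one or more
alignments, clade-conservation calls, cross-clade overlap tests and
cross-alignment robustness — and writes every stage's table plus a run
manifest (parameters, seeds, input checksums) sufficient to reproduce the
run byte-identically. Alignments and trees are always inputs, never
computed internally.

Sequences removed by screening or pruning are excluded from all
downstream tables but listed with their reasons; no sequence is dropped
silently.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .gene_structure import parse_gene_structures, parse_exon_table, introns_from_structure
from .introns import (
    AlignedSequence,
    cluster_introns,
    clade_conserved_positions,
    compare_clades,
    cross_alignment_robustness,
    map_marks,
    read_alignment_fasta,
    read_clade_table,
    render_intron_map,
)
from .screen import bovine_rhodopsin, read_domain_calls, screen_candidates
from .simulate import SimulationConfig, simulate_family
from .stability import (
    DEFAULT_MAX_TRIPLETS,
    DEFAULT_THRESHOLD,
    DEFAULT_VARIANT,
    leaf_stability_scores,
    prune_unstable,
    read_tree_set,
    tree_set_from_newicks,
)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "demo"]


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Inputs and parameters of one pipeline run.

    ``alignments`` maps a short name (e.g. the aligner used) to an
    aligned-FASTA path. ``gene_structures`` may be GFF3 or an exon-table
    TSV (by extension). ``reference`` defaults to the packaged bovine
    rhodopsin.
    """

    proteins: str = ""
    alignments: dict[str, str] = field(default_factory=dict)
    gene_structures: str = ""
    trees: Optional[str] = None
    clades: str = ""
    reference: Optional[str] = None
    domain_calls: Optional[str] = None
    outdir: str = "opsintron-out"

    min_length: int = 160
    apply_screen: bool = True
    stability_variant: str = DEFAULT_VARIANT
    stability_threshold: float = DEFAULT_THRESHOLD
    max_triplets: int = DEFAULT_MAX_TRIPLETS
    window: int = 0
    min_fraction: float = 0.9
    min_members: int = 2
    jaccard_min: float = 0.5
    seed: int = 0
    render: bool = False

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        required = {"proteins": self.proteins, "clades": self.clades}
        for name, path in required.items():
            if not path or not os.path.exists(path):
                raise PipelineError(f"missing input {name!r}: {path!r}")
        if not self.alignments:
            raise PipelineError("at least one alignment is required")
        optional = dict(self.alignments)
        if self.gene_structures:
            optional["gene_structures"] = self.gene_structures
        if self.trees:
            optional["trees"] = self.trees
        if self.domain_calls:
            optional["domain_calls"] = self.domain_calls
        for name, path in optional.items():
            if not os.path.exists(path):
                raise PipelineError(f"input file for {name!r} not found: {path!r}")
        if not 0 < self.min_fraction <= 1:
            raise PipelineError("min_fraction must be in (0,1]")
        if self.window < 0 or self.min_members < 0 or self.min_length < 0:
            raise PipelineError("window/min_members/min_length must be >= 0")


@dataclass
class ReportBundle:
    screen: pd.DataFrame
    stability: Optional[pd.DataFrame]
    pruned: list[str]
    excluded: pd.DataFrame  # sequence, stage, reason
    conserved: pd.DataFrame
    clusters: pd.DataFrame
    overlap: pd.DataFrame
    robustness: pd.DataFrame
    manifest: dict

    def conserved_counts(self) -> dict[str, int]:
        """Conserved-position count per clade in the first alignment."""
        if self.conserved.empty:
            return {}
        first = self.manifest["parameters"]["alignment_names"][0]
        sub = self.conserved[self.conserved.alignment == first]
        return sub.groupby("clade").size().to_dict()


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: str, params: dict) -> None:
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(params, sort_keys=True) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run all stages in order and write the report tables."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    params = {
        k: v
        for k, v in asdict(config).items()
        if k not in ("proteins", "alignments", "gene_structures", "trees",
                     "clades", "reference", "domain_calls", "outdir")
    }

    proteins = {
        r.id: str(r.seq).rstrip("*")
        for r in SeqIO.parse(config.proteins, "fasta")
    }
    if not proteins:
        raise PipelineError(f"no sequences in {config.proteins}")
    clade_map = read_clade_table(config.clades)
    reference = None
    if config.reference:
        reference = str(next(SeqIO.parse(config.reference, "fasta")).seq)

    exclusions: list[dict] = []

    # stage 1: diagnostic screening
    domain_calls = (
        read_domain_calls(config.domain_calls) if config.domain_calls else None
    )
    screen_df = screen_candidates(
        proteins,
        reference=reference,
        min_length=config.min_length,
        domain_calls=domain_calls,
    )
    if config.apply_screen:
        retained = set(screen_df.loc[screen_df.retained, "candidate_id"])
        for _, row in screen_df[~screen_df.retained].iterrows():
            exclusions.append(
                {"sequence": row.candidate_id, "stage": "screen",
                 "reason": row.exclusion_reasons}
            )
    else:
        # screen recorded but not gating (synthetic, non-opsin families)
        retained = set(screen_df.candidate_id)

    # stage 2: leaf-stability pruning (when a tree set is supplied)
    stability_df = None
    pruned: list[str] = []
    if config.trees:
        ts = read_tree_set(config.trees)
        table = leaf_stability_scores(
            ts,
            variant=config.stability_variant,
            max_triplets_per_taxon=config.max_triplets,
            seed=config.seed,
        )
        stability_df = table.to_frame()
        _, removed = prune_unstable(table, config.stability_threshold)
        pruned = [t for t in removed if t in retained]
        for t in pruned:
            exclusions.append(
                {"sequence": t, "stage": "leaf_stability",
                 "reason": f"score {table.scores[t]:.3f} < "
                           f"{config.stability_threshold}"}
            )
        retained -= set(removed)

    # stage 3: intron marks from gene structures
    marks = []
    if config.gene_structures:
        if config.gene_structures.endswith((".tsv", ".txt", ".tab")):
            structures = parse_exon_table(config.gene_structures)
        else:
            structures = parse_gene_structures(config.gene_structures)
        for s in structures:
            if s.gene_id in retained:
                marks.extend(introns_from_structure(s))

    # stage 4: per-alignment mapping / clustering / conservation
    alignment_rows: dict[str, list[AlignedSequence]] = {}
    for name, path in sorted(config.alignments.items()):
        rows = read_alignment_fasta(path, proteins=proteins)
        ids = {r.seq_id for r in rows}
        missing = sorted(set(proteins) - ids)
        if missing:
            raise PipelineError(
                f"alignment {name!r} is missing sequences: {missing}"
            )
        alignment_rows[name] = [r for r in rows if r.seq_id in retained]

    # excluded sequences leave the dataset entirely: conservation
    # fractions are relative to the retained members of each clade
    retained_clade_map = {t: c for t, c in clade_map.items() if t in retained}
    clades = sorted(set(retained_clade_map.values()))
    cluster_records, conserved_records, overlap_records = [], [], []
    reports_by_alignment: dict[str, dict[str, object]] = {}
    for name, rows in sorted(alignment_rows.items()):
        mapped = map_marks(marks, rows)
        clusters = cluster_introns(mapped, window=config.window)
        for i, cl in enumerate(clusters):
            cluster_records.append(
                {
                    "alignment": name,
                    "cluster_id": f"{name}.c{i + 1}",
                    "column": cl.column,
                    "phase": cl.phase,
                    "size": cl.size,
                    "members": ",".join(sorted(cl.seq_ids)),
                }
            )
        reports = {}
        for clade in clades:
            rep = clade_conserved_positions(
                clusters,
                retained_clade_map,
                clade,
                min_fraction=config.min_fraction,
                min_members=config.min_members,
                window=config.window,
            )
            reports[clade] = rep
            for pos in rep.conserved:
                conserved_records.append(
                    {
                        "alignment": name,
                        "clade": clade,
                        "column": pos.cluster.column,
                        "phase": pos.cluster.phase,
                        "carriers": len(pos.carriers),
                        "clade_size": pos.clade_size,
                        "fraction": round(pos.fraction, 4),
                        "carrier_ids": ",".join(pos.carriers),
                        "other_carriers": ",".join(pos.other_carriers),
                    }
                )
        reports_by_alignment[name] = reports
        for i, ca in enumerate(clades):
            for cb in clades[i + 1 :]:
                overlap = compare_clades(
                    reports[ca], reports[cb], window=config.window
                )
                for (ka, kb, d) in overlap.nearest:
                    overlap_records.append(
                        {
                            "alignment": name,
                            "clade_a": ca,
                            "clade_b": cb,
                            "column_a": ka[0],
                            "phase_a": ka[1],
                            "column_b": kb[0],
                            "phase_b": kb[1],
                            "distance": d,
                            "overlaps": d <= config.window and ka[1] == kb[1],
                        }
                    )

    # stage 5: robustness across alignments
    robustness_records = []
    if len(alignment_rows) >= 1 and marks:
        retained_marks = [m for m in marks if m.gene_id in retained]
        rob = cross_alignment_robustness(
            alignment_rows,
            retained_marks,
            retained_clade_map,
            clades=clades,
            min_fraction=config.min_fraction,
            min_members=config.min_members,
            window=config.window,
            jaccard_min=config.jaccard_min,
        )
        for gi, group in enumerate(rob.groups):
            for name, pos in sorted(group["by_alignment"].items()):
                robustness_records.append(
                    {
                        "group": gi + 1,
                        "clade": group["clade"],
                        "alignment": name,
                        "column": pos.cluster.column,
                        "phase": pos.cluster.phase,
                        "robust": group["robust"],
                        "missing_in": ",".join(group["missing_in"]),
                    }
                )

    screen_df = screen_df.copy()
    stability_frame = stability_df if stability_df is not None else pd.DataFrame(
        columns=["taxon", "score", "n_triplets", "variant"]
    )
    excluded_df = pd.DataFrame(
        exclusions, columns=["sequence", "stage", "reason"]
    )
    clusters_df = pd.DataFrame(
        cluster_records,
        columns=["alignment", "cluster_id", "column", "phase", "size", "members"],
    )
    conserved_df = pd.DataFrame(
        conserved_records,
        columns=["alignment", "clade", "column", "phase", "carriers",
                 "clade_size", "fraction", "carrier_ids", "other_carriers"],
    )
    overlap_df = pd.DataFrame(
        overlap_records,
        columns=["alignment", "clade_a", "clade_b", "column_a", "phase_a",
                 "column_b", "phase_b", "distance", "overlaps"],
    )
    robustness_df = pd.DataFrame(
        robustness_records,
        columns=["group", "clade", "alignment", "column", "phase", "robust",
                 "missing_in"],
    )

    input_paths = {"proteins": config.proteins, "clades": config.clades}
    input_paths.update(
        {f"alignment:{k}": v for k, v in sorted(config.alignments.items())}
    )
    for key in ("gene_structures", "trees", "reference", "domain_calls"):
        value = getattr(config, key)
        if value:
            input_paths[key] = value
    manifest = {
        "tool": "opsintron",
        "version": __version__,
        "parameters": {
            **params,
            "alignment_names": sorted(config.alignments),
        },
        "inputs": {k: {"path": v, "sha256": _sha256(v)}
                   for k, v in input_paths.items()},
        "counts": {
            "input_sequences": len(proteins),
            "retained": len(retained),
            "excluded": len(exclusions),
        },
    }

    bundle = ReportBundle(
        screen=screen_df,
        stability=stability_frame,
        pruned=pruned,
        excluded=excluded_df,
        conserved=conserved_df,
        clusters=clusters_df,
        overlap=overlap_df,
        robustness=robustness_df,
        manifest=manifest,
    )

    out = config.outdir
    _write_table(screen_df, os.path.join(out, "screen.tsv"), params)
    _write_table(stability_frame, os.path.join(out, "stability.tsv"), params)
    _write_table(excluded_df, os.path.join(out, "excluded.tsv"), params)
    _write_table(clusters_df, os.path.join(out, "clusters.tsv"), params)
    _write_table(conserved_df, os.path.join(out, "conserved.tsv"), params)
    _write_table(overlap_df, os.path.join(out, "overlap.tsv"), params)
    _write_table(robustness_df, os.path.join(out, "robustness.tsv"), params)
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    if config.render and alignment_rows:
        first = sorted(alignment_rows)[0]
        rows = alignment_rows[first]
        mapped = map_marks([m for m in marks if m.gene_id in retained], rows)
        conserved_first = [
            pos
            for rep in reports_by_alignment[first].values()
            for pos in rep.conserved
        ]
        render_intron_map(
            rows,
            mapped,
            clade_map,
            os.path.join(out, "intron_map.png"),
            conserved=conserved_first,
        )

    return bundle


def demo(seed: int = 0, outdir: str = "opsintron-demo", render: bool = True,
         rogue: bool = True) -> ReportBundle:
    """Generate a small synthetic family and run the full pipeline on it.

    Two clades (clade A with three planted intron positions, clade B with
    two, at non-overlapping columns) plus an optional rogue taxon whose
    bootstrap attachment is random; the pipeline should prune the rogue,
    recover the planted conserved positions exactly and report zero
    cross-clade overlap.
    """
    os.makedirs(outdir, exist_ok=True)
    data_dir = os.path.join(outdir, "data")
    config = SimulationConfig(
        seed=seed,
        n_clades=2,
        seqs_per_clade=8,
        protein_length=240,
        substitution_rate=0.05,
        planted_introns=[[(60, 0), (120, 1), (180, 2)], [(90, 0), (200, 1)]],
        n_trees=100,
        rogue_taxa=["cladeA_s01"] if rogue else [],
    )
    dataset = simulate_family(config)
    paths = dataset.write(data_dir)
    pipe_config = PipelineConfig(
        proteins=paths["proteins.fasta"],
        alignments={"true": paths["alignment.true.fasta"]},
        gene_structures=paths["structures.gff3"],
        trees=paths["trees.nwk"],
        clades=paths["clades.tsv"],
        outdir=outdir,
        seed=seed,
        render=render,
        apply_screen=False,
    )
    return run_pipeline(pipe_config)
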