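"""End-to-end orchestration: proteomes/trees in, delineation artifacts out.

``run_pipeline`` wires the library stages together in the order the analysis
proceeds: AAI matrix from proteomes (or a precomputed matrix), evolutionary
distances per tree (or from an mldist file), pairwise consensus degrees and
a majority-rule census tree when several trees are given, hierarchical
family/genus delineation on the primary (first) tree, separation statistics
with derived thresholds, monophyly checks against a taxonomy mapping, and
ANI/dDDH synonymy flags. Stages whose inputs are absent are skipped; the
pipeline itself draws no random numbers, so a rerun on the same inputs
reproduces every output byte (timestamps live only in the log).
"""

from __future__ import annotations

import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .aai import AaiParams, aai_matrix
from .core import LabeledMatrix, PhyloTree
from .delineate import (
    ThresholdRule,
    TaxonPartition,
    derive_threshold,
    hierarchical_delineate,
    intra_inter_split,
    welch_t_test,
)
from .errors import TaxodelimError
from .seqio import (
    read_newick,
    read_proteome_dir,
    read_square_matrix,
    read_taxonomy_mapping,
    newick_string,
    write_matrix,
)
from .synonymy import flag_synonym_pairs
from .treestats import consensus_degree, ed_matrix, majority_consensus, monophyly_report, root_with_outgroup

__all__ = ["RunConfig", "RunReport", "run_pipeline", "write_partition", "read_partition"]

log = logging.getLogger("taxodelim")


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    out_dir: str
    proteome_dir: str | None = None
    trees: list[str] = field(default_factory=list)
    mldist: str | None = None
    aai: str | None = None  # precomputed AAI matrix (tsv_long, fraction)
    ani: str | None = None  # percent tsv_long
    ddh: str | None = None  # percent tsv_long
    mapping: str | None = None
    outgroup: str | None = None
    family_aai: float = 0.6
    family_ed: float = 0.5
    genus_aai: float = 0.7
    genus_ed: float = 0.4
    support_min: float = 70.0
    ani_cutoff: float = 96.0
    ddh_cutoff: float = 70.0
    min_identity: float = 0.30
    min_coverage_short: float = 0.70
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for name in ("proteome_dir", "mldist", "aai", "ani", "ddh", "mapping"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise TaxodelimError(f"config path {name}={value!r} does not exist")
        for tree in self.trees:
            if not Path(tree).exists():
                raise TaxodelimError(f"tree file {tree!r} does not exist")
        for name, value, lo, hi in (
            ("family_aai", self.family_aai, 0, 1),
            ("genus_aai", self.genus_aai, 0, 1),
            ("support_min", self.support_min, 0, 100),
            ("ani_cutoff", self.ani_cutoff, 0, 100),
            ("ddh_cutoff", self.ddh_cutoff, 0, 100),
        ):
            if not lo <= value <= hi:
                raise TaxodelimError(f"threshold {name}={value} outside [{lo}, {hi}]")


@dataclass
class RunReport:
    outputs: dict[str, str]
    summary: dict


def write_partition(partition: TaxonPartition, path: str | Path) -> None:
    lines = ["leaf\tgroup"]
    for name in sorted(partition.groups):
        for leaf in sorted(partition.groups[name]):
            lines.append(f"{leaf}\t{name}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_partition(path: str | Path, rank: str = "group") -> TaxonPartition:
    mapping: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or (i == 0 and line.startswith("leaf")):
            continue
        leaf, group = line.split("\t")[:2]
        mapping[leaf] = group
    return TaxonPartition.from_mapping(rank, mapping)


def _separation_block(matrix: LabeledMatrix, partition: TaxonPartition, direction: str) -> dict:
    rep = intra_inter_split(matrix, partition)
    block: dict = {
        "n_intra": int(rep.intra.size),
        "n_inter": int(rep.inter.size),
        "group_summaries": rep.group_summaries,
    }
    if rep.intra.size and rep.inter.size:
        block["intra_range"] = [float(rep.intra.min()), float(rep.intra.max())]
        block["inter_range"] = [float(rep.inter.min()), float(rep.inter.max())]
        block["derived_threshold"] = derive_threshold(rep.intra, rep.inter, direction)
        if rep.intra.size >= 2 and rep.inter.size >= 2:
            w = welch_t_test(rep.intra, rep.inter)
            block["welch"] = {"t": w.t, "df": w.df, "p": w.p, "p_display": w.p_display}
    return block


def run_pipeline(config: RunConfig) -> RunReport:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    log.addHandler(handler)
    outputs: dict[str, str] = {}
    summary: dict = {}

    def record(key: str, path: Path) -> None:
        outputs[key] = str(path)

    try:
        log.info(
            "taxodelim %s (python %s, numpy %s), seed %d",
            __version__, sys.version.split()[0], np.__version__, config.seed,
        )
        (out / "config.json").write_text(json.dumps(asdict(config), indent=2) + "\n")
        record("config", out / "config.json")

        # --- AAI -----------------------------------------------------------
        aai_mat: LabeledMatrix | None = None
        stage = "aai"
        if config.aai is not None:
            aai_mat = read_square_matrix(
                config.aai, "tsv_long", kind="similarity", scale="fraction"
            )
            log.info("loaded precomputed AAI for %d taxa", len(aai_mat.labels))
        elif config.proteome_dir is not None:
            proteomes = read_proteome_dir(config.proteome_dir)
            params = AaiParams(
                min_identity=config.min_identity,
                min_coverage_short=config.min_coverage_short,
            )
            aai_mat = aai_matrix(proteomes, params)
            log.info("computed AAI over %d proteomes", len(proteomes))
        if aai_mat is not None:
            write_matrix(aai_mat, out / "aai.tsv", "tsv_long")
            record("aai", out / "aai.tsv")

        # --- Trees and ED --------------------------------------------------
        stage = "trees"
        trees: list[tuple[str, PhyloTree]] = []
        for path in config.trees:
            name = Path(path).stem
            t = read_newick(path)
            if config.outgroup is not None:
                t = root_with_outgroup(t, config.outgroup)
            trees.append((name, t))
        ed_mats: dict[str, LabeledMatrix] = {}
        stage = "ed"
        if config.mldist is not None:
            ed_mats["mldist"] = read_square_matrix(config.mldist, "mldist")
        for name, t in trees:
            if t.has_branch_lengths():
                ed_mats[name] = ed_matrix(t)
        for name, mat in ed_mats.items():
            write_matrix(mat, out / f"ed_{name}.tsv", "tsv_long")
            record(f"ed_{name}", out / f"ed_{name}.tsv")

        # --- Consensus degree & census tree --------------------------------
        stage = "cd"
        if len(trees) >= 2:
            rows = ["tree_a\ttree_b\tn_shared\tdenominator\tcd"]
            for i in range(len(trees)):
                for j in range(i + 1, len(trees)):
                    rep = consensus_degree(
                        trees[i][1], trees[j][1], trees[i][0], trees[j][0]
                    )
                    rows.append(
                        f"{rep.tree_a}\t{rep.tree_b}\t{rep.n_shared}"
                        f"\t{rep.denominator}\t{rep.cd:.4f}"
                    )
            (out / "cd.tsv").write_text("\n".join(rows) + "\n")
            record("cd", out / "cd.tsv")
            census = majority_consensus([t for _, t in trees])
            (out / "census.nwk").write_text(
                newick_string(census, recovery_as_label=True) + "\n"
            )
            record("census", out / "census.nwk")

        # --- Delineation ----------------------------------------------------
        stage = "delineate"
        if trees and aai_mat is not None and ed_mats:
            primary_name, primary = trees[0]
            ed_for_rules = ed_mats.get("mldist", ed_mats.get(primary_name))
            matrices = {"AAI": aai_mat, "ED": ed_for_rules}
            fam_rules = [
                ThresholdRule("AAI", "similarity", config.family_aai),
                ThresholdRule("ED", "distance", config.family_ed),
            ]
            gen_rules = [
                ThresholdRule("AAI", "similarity", config.genus_aai),
                ThresholdRule("ED", "distance", config.genus_ed),
            ]
            parts = hierarchical_delineate(
                primary, fam_rules, gen_rules, matrices, config.support_min
            )
            write_partition(parts["family"], out / "partition_family.tsv")
            write_partition(parts["genus"], out / "partition_genus.tsv")
            record("partition_family", out / "partition_family.tsv")
            record("partition_genus", out / "partition_genus.tsv")
            summary["n_families"] = parts["family"].n_groups
            summary["n_genera"] = parts["genus"].n_groups
            log.info(
                "delineated %d families / %d genera on tree %s",
                parts["family"].n_groups, parts["genus"].n_groups, primary_name,
            )

            stage = "stats"
            sep = {
                "AAI": _separation_block(aai_mat, parts["family"], "similarity"),
                "ED": _separation_block(ed_for_rules, parts["family"], "distance"),
            }
            (out / "separation_report.json").write_text(json.dumps(sep, indent=2) + "\n")
            record("separation_report", out / "separation_report.json")
            summary["separation"] = {
                m: {
                    k: blk[k]
                    for k in ("derived_threshold", "welch")
                    if k in blk
                }
                for m, blk in sep.items()
            }

            stage = "monophyly"
            if config.mapping is not None:
                mapping_df = read_taxonomy_mapping(config.mapping)
                rows = ["rank\ttaxon\tmonophyletic\tn_leaves\tsmallest_containing_clade"]
                for rank in ("genus", "family"):
                    rep = monophyly_report(primary, mapping_df[rank].to_dict())
                    for taxon, info in rep.items():
                        rows.append(
                            f"{rank}\t{taxon}\t{info['monophyletic']}"
                            f"\t{info['n_leaves']}\t{info['smallest_containing_clade']}"
                        )
                (out / "monophyly.tsv").write_text("\n".join(rows) + "\n")
                record("monophyly", out / "monophyly.tsv")

        # --- Synonymy -------------------------------------------------------
        stage = "synonymy"
        if config.ani is not None and config.ddh is not None:
            ani = read_square_matrix(config.ani, "tsv_long", kind="similarity", scale="percent")
            ddh = read_square_matrix(config.ddh, "tsv_long", kind="similarity", scale="percent")
            calls = flag_synonym_pairs(ani, ddh, config.ani_cutoff, config.ddh_cutoff)
            rows = ["taxon_a\ttaxon_b\tani\tddh\tverdict"]
            for c in calls:
                rows.append(f"{c.taxon_a}\t{c.taxon_b}\t{c.ani:.4f}\t{c.ddh:.4f}\t{c.verdict}")
            (out / "synonyms.tsv").write_text("\n".join(rows) + "\n")
            record("synonyms", out / "synonyms.tsv")
            summary["n_synonym_pairs"] = len(calls)

    except TaxodelimError as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise TaxodelimError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    (out / "report.json").write_text(
        json.dumps({"outputs": outputs, "summary": summary}, indent=2, default=str) + "\n"
    )
    return RunReport(outputs=outputs, summary=summary)
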