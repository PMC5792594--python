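"""End-to-end orchestration: generate-or-load inputs, mine superfamily
members, partition subfamilies, call clade specificity, rank candidates,
and emit a structured report.

The pipeline is a plain library function driven by a single
:class:`PipelineConfig` (constructible in code or from YAML). Stages run
in a fixed order (mine -> cluster -> specificity -> rank); every stage's
record counts and the full parameter set are echoed into the report, and
all randomness flows from the seeds in the config, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import domains, expression, phylo, specificity
from .simulate import (
    ExpressionTable,
    FamilySpec,
    ProteinRecord,
    SyntheticBundle,
    default_design,
    default_family_specs,
    parse_fasta_header,
    read_fixture,
    simulate_bundle,
    write_fixture,
)

__all__ = ["PipelineConfig", "StageError", "RunReport", "run_pipeline"]

logger = logging.getLogger("clademiner.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one run needs.

    ``mode`` is "synthetic" (inputs simulated from ``seed``) or "files"
    (``input_dir`` must hold a fixture as written by
    :func:`clademiner.simulate.write_fixture`). Defaults mirror the
    published analysis: E-value cutoff 1e-10, length window (350, 650),
    identity threshold tau = 0.55, shortlist size 36.
    """

    outdir: str
    mode: str = "synthetic"
    input_dir: str | None = None
    ingroup: list[str] = field(default_factory=lambda: [f"ing{i + 1}" for i in range(5)])
    focal_species: str = "ing1"
    tau: float = 0.55
    top_k: int = 36
    e_max: float = 1e-10
    len_lo: int = 350
    len_hi: int = 650
    n_shuffles: int = 200
    seed: int = 0
    decoy_count: int = 40
    n_wild: int = 5
    n_cultivated: int = 6
    family_specs: list[dict] | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"synthetic", "files"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "files":
            if self.input_dir is None:
                raise ValueError("files mode requires input_dir")
            missing = _missing_inputs(Path(self.input_dir))
            if missing:
                raise ValueError(f"missing input files: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def search_config(self) -> domains.SearchConfig:
        return domains.SearchConfig(
            e_max=self.e_max,
            len_lo=self.len_lo,
            len_hi=self.len_hi,
            n_shuffles=self.n_shuffles,
            seed=self.seed,
        )

    def echo(self) -> dict:
        """Parameters echoed verbatim into the report (output path
        excluded so reruns into different directories stay comparable)."""
        payload = asdict(self)
        payload.pop("outdir")
        return payload


def _missing_inputs(input_dir: Path) -> list[str]:
    missing = []
    if not (input_dir / "proteomes").is_dir() or not list(
        (input_dir / "proteomes").glob("*.fasta")
    ):
        missing.append(str(input_dir / "proteomes" / "*.fasta"))
    for name in ("truth.json", "expression.tsv"):
        if not (input_dir / name).exists():
            missing.append(str(input_dir / name))
    return missing


@dataclass
class RunReport:
    parameters: dict
    stages: list[dict]
    class_counts: dict
    shortlist: list[dict]
    rank_sum: dict | None
    warnings: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    def to_text(self) -> str:
        lines = ["clademiner pipeline report", "=" * 30]
        for stage in self.stages:
            counts = ", ".join(f"{k}={v}" for k, v in stage.items() if k != "name")
            lines.append(f"[{stage['name']}] {counts}")
        cc = self.class_counts
        lines.append(
            f"classes: {cc['n_specific_subfamilies']} specific / "
            f"{cc['n_shared_subfamilies']} shared subfamilies; focal genes "
            f"{cc['n_specific_genes_focal']} specific + "
            f"{cc['n_shared_genes_focal']} shared = {cc['n_genes_focal']}"
        )
        if self.rank_sum:
            lines.append(
                f"rank-sum specific vs shared: U={self.rank_sum['statistic']:g}, "
                f"p={self.rank_sum['p_value']:.3g} ({self.rank_sum['method']})"
            )
        lines.append(f"shortlist ({len(self.shortlist)} genes):")
        for entry in self.shortlist:
            lines.append(
                f"  {entry['rank']:>3}. {entry['gene']} [{entry['subfamily_id']}] "
                f"mean={entry['mean_all']:.2f}"
            )
        for w in self.warnings:
            lines.append(f"warning: {w}")
        lines.append(cc["caveat"])
        return "\n".join(lines) + "\n"


def _load_inputs(config: PipelineConfig, outdir: Path) -> SyntheticBundle:
    if config.mode == "synthetic":
        specs = (
            [FamilySpec(**fs) for fs in config.family_specs]
            if config.family_specs
            else default_family_specs()
        )
        design = default_design()
        if set(config.ingroup) != set(design.ingroup_ids):
            raise ValueError(
                "synthetic mode uses the default design; ingroup must be "
                f"{design.ingroup_ids}"
            )
        bundle = simulate_bundle(
            design=design,
            specs=specs,
            decoy_count=config.decoy_count,
            n_wild=config.n_wild,
            n_cultivated=config.n_cultivated,
            seed=config.seed,
        )
        write_fixture(bundle, outdir / "inputs")
        return bundle
    return read_fixture(config.input_dir)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run mine -> cluster -> specificity -> rank and write artifacts.

    Intermediate TSV/Newick artifacts and the final ``report.json`` /
    ``report.txt`` are written under ``config.outdir``. Raises
    :class:`StageError` naming the failing stage; artifacts of completed
    stages are retained for debugging.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    stages: list[dict] = []

    try:
        bundle = _load_inputs(config, outdir)
    except Exception as exc:
        raise StageError("inputs", exc) from exc

    proteins = bundle.all_proteins()
    search_cfg = config.search_config()

    # --- stage 1: mine ----------------------------------------------------
    logger.info("[mine] scanning %d proteins", len(proteins))
    try:
        profiles = [
            domains.build_profile(aln)
            for _, aln in sorted(bundle.seed_alignments.items())
        ]
        hits = domains.search_proteome(profiles, proteins, search_cfg)
        kept = domains.filter_hits(hits, search_cfg)
        domains.write_hits_tsv(kept, outdir / "hits.tsv")
    except Exception as exc:
        raise StageError("mine", exc) from exc
    stages.append(
        {
            "name": "mine",
            "proteins_scanned": len(proteins),
            "hits": len(hits),
            "hits_kept": len(kept),
        }
    )
    if not kept:
        raise StageError("mine", RuntimeError("no hits survived filtering"))

    # --- stage 2: cluster -------------------------------------------------
    logger.info("[cluster] %d superfamily members", len(kept))
    try:
        by_gene = {p.gene: p for p in proteins}
        members = [by_gene[h.gene] for h in kept]
        idmat = phylo.build_identity_matrix(members)
        tree = phylo.subfamily_tree(idmat)
        assignment = phylo.partition_subfamilies(
            tree, idmat, {p.gene: p.species for p in members}, tau=config.tau
        )
        (outdir / "members_tree.nwk").write_text(tree.to_newick() + "\n")
        _write_assignment_tsv(assignment, outdir / "subfamilies.tsv")
    except Exception as exc:
        raise StageError("cluster", exc) from exc
    stages.append(
        {
            "name": "cluster",
            "members": len(members),
            "subfamilies": len(assignment.subfamily_ids),
        }
    )

    # --- stage 3: specificity ---------------------------------------------
    try:
        calls = specificity.call_clade_specific(assignment, set(config.ingroup))
        counts = specificity.specificity_summary(
            calls, assignment, config.focal_species
        )
        _write_calls_tsv(calls, outdir / "specificity.tsv")
    except Exception as exc:
        raise StageError("specificity", exc) from exc
    stages.append(
        {
            "name": "specificity",
            "subfamilies": len(calls),
            "specific": sum(c.specific for c in calls),
            "shared": sum(not c.specific for c in calls),
        }
    )

    # --- stage 4: rank ----------------------------------------------------
    try:
        if bundle.expression is None:
            raise RuntimeError("no expression table available")
        means = expression.group_mean_expression(bundle.expression)
        ranking = expression.rank_candidates(
            calls, means, assignment, top_k=config.top_k
        )
        rank_sum = None
        try:
            rs = expression.compare_specific_vs_nonspecific(means, calls, assignment)
            rank_sum = asdict(rs)
        except ValueError as exc:
            warnings_log.append(f"rank-sum comparison skipped: {exc}")
        ranking.entries.to_csv(
            outdir / "ranking.tsv", sep="\t", index=False, float_format="%.6g"
        )
    except Exception as exc:
        raise StageError("rank", exc) from exc
    stages.append(
        {
            "name": "rank",
            "candidates": int(
                sum(
                    len(assignment.members[c.subfamily_id])
                    for c in calls
                    if c.specific
                )
            ),
            "shortlist": len(ranking.entries),
        }
    )

    report = RunReport(
        parameters=config.echo(),
        stages=stages,
        class_counts={
            "n_specific_subfamilies": counts.n_specific_subfamilies,
            "n_shared_subfamilies": counts.n_shared_subfamilies,
            "n_specific_genes_focal": counts.n_specific_genes_focal,
            "n_shared_genes_focal": counts.n_shared_genes_focal,
            "n_genes_focal": counts.n_genes_focal,
            "focal_species": counts.focal_species,
            "caveat": counts.caveat,
        },
        shortlist=ranking.entries.to_dict(orient="records"),
        rank_sum=rank_sum,
        warnings=warnings_log,
    )
    (outdir / "report.json").write_text(report.to_json())
    (outdir / "report.txt").write_text(report.to_text())
    return report


def _write_assignment_tsv(assignment, path) -> None:
    lines = ["gene\tsubfamily_id\tspecies"]
    for sf_id in assignment.subfamily_ids:
        for g in assignment.members[sf_id]:
            lines.append(f"{g}\t{sf_id}\t{assignment.species_of[g]}")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_calls_tsv(calls, path) -> None:
    lines = ["subfamily_id\tspecific\tingroup_species\toutgroup_species"]
    for c in calls:
        lines.append(
            f"{c.subfamily_id}\t{int(c.specific)}\t"
            f"{c.ingroup_species_present}\t{c.outgroup_species_present}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
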