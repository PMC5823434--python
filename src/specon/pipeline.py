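"""End-to-end pipeline orchestration with a flat JSON config and manifest.

``run_pipeline`` ties the stages together: load (or synthesise) a paralog
alignment and per-member ortholog alignments, profile them, compute SC
tables and Fig-4-style summaries, build PSSMs / master matrix / clusters,
and score any binding matrices. Every run writes a manifest with the config,
seeds, input checksums and package version so deterministic stages re-run
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .alignment_io import (
    Alignment,
    build_canonical_map,
    read_alignment,
    write_alignment,
)
from .conservation import (
    GAP_THRESHOLD,
    INSERTION_CUTOFF,
    SC_CUTOFF,
    DEFAULT_SURFACES,
    EquivalencyScheme,
    family_position_average,
    profile_alignment,
    sc_profile,
    summarize_domain,
)
from .pssm_cluster import (
    build_master_matrix,
    build_pssm,
    cluster_hierarchical,
    cluster_kmeans,
    subset_surface,
)
from .binding_specificity import (
    BF_CUTOFF,
    MIN_SUM,
    DEFAULT_MERGE_RULES,
    binding_fraction,
    call_specific,
    merge_paralogs,
    read_binding_matrix,
    summarize_domain_binding,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Flat pipeline configuration; defaults are the published constants."""

    paralog_path: str | None = None
    ortholog_dir: str | None = None  # one file per member: <member>.fasta
    binding_dir: str | None = None  # one TSV per species
    reference_id: str | None = None
    domain_span: tuple[int, int] | None = None
    alignment_format: str = "fasta"
    gap_threshold: float = GAP_THRESHOLD
    sc_cutoff: float = SC_CUTOFF
    insertion_cutoff: float = INSERTION_CUTOFF
    min_sum: float = MIN_SUM
    bf_cutoff: float = BF_CUTOFF
    kmeans_k: int = 4
    seed: int = 0
    out_dir: str = "specon_out"

    def __post_init__(self) -> None:
        for name in ("gap_threshold", "sc_cutoff", "insertion_cutoff", "min_sum",
                     "bf_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        if data.get("domain_span") is not None:
            data["domain_span"] = tuple(data["domain_span"])
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: RunConfig):
    if config.paralog_path is None or config.ortholog_dir is None:
        raise ValueError("config must name a paralog alignment and an ortholog dir")
    paralog = read_alignment(config.paralog_path, config.alignment_format,
                             kind="paralog")
    members = [r.id for r in paralog.rows]
    ortho_dir = Path(config.ortholog_dir)
    suffix = {"fasta": ".fasta", "clustal": ".aln"}[config.alignment_format]
    orthologs: dict[str, Alignment] = {}
    for m in members:
        path = ortho_dir / f"{m}{suffix}"
        if not path.exists():
            raise FileNotFoundError(
                f"missing ortholog alignment for domain {m!r}: {path}"
            )
        orthologs[m] = read_alignment(path, config.alignment_format, kind="ortholog")
    return paralog, orthologs


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write TSV outputs plus ``manifest.json``.

    Returns the output directory. Stage failures propagate with the stage
    named in the exception message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = EquivalencyScheme()

    stage = "load"
    try:
        paralog, orthologs = _load_inputs(config)

        stage = "conservation"
        # Canonical frame of the paralog alignment comes from its first row
        # when no reference is named (synthetic references are ungapped).
        ref = config.reference_id or paralog.rows[0].id
        par_map = build_canonical_map(paralog, ref, config.domain_span)
        par_profiles = profile_alignment(paralog, par_map, scheme,
                                         config.gap_threshold)
        profiles = []
        pssms = []
        for member, aln in orthologs.items():
            omap = build_canonical_map(aln, member, config.domain_span)
            oprofiles = profile_alignment(aln, omap, scheme, config.gap_threshold)
            profile = sc_profile(par_profiles, oprofiles, member)
            profiles.append(profile)
            profile.to_frame().to_csv(out / f"sc_{member}.tsv", sep="\t",
                                      index=False, float_format="%.6g")
            pssms.append(build_pssm(aln, omap, scheme, domain_name=member))

        family = pd.DataFrame({p.domain_name: p.sc_series() for p in profiles}).T
        family.to_csv(out / "family_sc_matrix.tsv", sep="\t",
                      index_label="domain", float_format="%.6g")
        family_position_average(profiles).to_csv(
            out / "family_position_average.tsv", sep="\t",
            index_label="position", float_format="%.6g")

        summary_rows = []
        for p in profiles:
            s = summarize_domain(p, sc_cutoff=config.sc_cutoff,
                                 insertion_cutoff=config.insertion_cutoff)
            row = {"domain": s.domain_name}
            row.update({f"avg_sc_{k}": v for k, v in s.avg_sc.items()})
            row.update({f"high_sc_{k}": v for k, v in s.high_sc.items()})
            row.update({f"ins_{k}": v for k, v in s.conserved_insertions.items()})
            summary_rows.append(row)
        pd.DataFrame(summary_rows).to_csv(out / "domain_summary.tsv", sep="\t",
                                          index=False, float_format="%.6g")

        stage = "pssm_cluster"
        master = build_master_matrix(pssms)
        master.data.to_csv(out / "master_matrix.tsv", sep="\t",
                           index_label="domain", float_format="%.10g")
        for surf_name in ("SI", "SII"):
            sub = subset_surface(master, DEFAULT_SURFACES[surf_name])
            km = cluster_kmeans(sub, k=min(config.kmeans_k, len(sub.domains)),
                                seed=config.seed, surface_name=surf_name)
            km.labels.to_csv(out / f"kmeans_{surf_name}.tsv", sep="\t",
                             index_label="domain")
            hier = cluster_hierarchical(sub, surface_name=surf_name)
            (out / f"dendrogram_{surf_name}.nwk").write_text(hier.newick + "\n")

        stage = "binding"
        binding_outputs = []
        if config.binding_dir is not None:
            tables = []
            for path in sorted(Path(config.binding_dir).glob("*.tsv")):
                if path.name.startswith("truth_"):
                    continue
                matrix = read_binding_matrix(path)
                merged = merge_paralogs(matrix, DEFAULT_MERGE_RULES)
                table = binding_fraction(merged, min_sum=config.min_sum)
                tables.append(table)
                table.bf.to_csv(out / f"bf_{table.species}.tsv", sep="\t",
                                index_label="peptide_id", float_format="%.6g")
                calls = call_specific(table, cutoff=config.bf_cutoff)
                calls.to_csv(out / f"specific_calls_{table.species}.tsv",
                             sep="\t", index=False, float_format="%.6g")
            domains = sorted({d for t in tables for d in t.domains})
            rows = []
            for d in domains:
                s = summarize_domain_binding(tables, d, cutoff=config.bf_cutoff)
                rows.append({
                    "domain": s.domain,
                    "n_peptides": s.n_specific_peptides,
                    "best_peptide": s.best_peptide,
                    "bf_specific": s.bf_specific,
                    "species": f"{s.n_species_specific}/{s.n_species_with_data}",
                })
            pd.DataFrame(rows).to_csv(out / "binding_summary.tsv", sep="\t",
                                      index=False, float_format="%.6g")
            binding_outputs = [t.species for t in tables]
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    inputs = {}
    for p in [config.paralog_path, *sorted(
            str(f) for f in Path(config.ortholog_dir).iterdir())]:
        inputs[str(p)] = _sha256(Path(p))
    if config.binding_dir is not None:
        for f in sorted(Path(config.binding_dir).glob("*.tsv")):
            inputs[str(f)] = _sha256(f)
    manifest = {
        "version": __version__,
        "config": json.loads(config.to_json()),
        "inputs": inputs,
        "n_domains": len(orthologs),
        "binding_species": binding_outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return out
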