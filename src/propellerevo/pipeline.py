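"""Workflow orchestration: reconstruction/design, genomic clock scan and
curve-fitting runs with reproducible configuration and provenance.

Each workflow is a plain function over a :class:`PipelineConfig`; the
command-line interface in :mod:`propellerevo.cli` is a thin wrapper around
these functions.  Every run writes a ``provenance.json`` with the config
hash, seed and package version, making runs byte-reproducible given the
same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ancestral import (AncestralPosterior, align_motifs, build_tree,
                        posterior_to_tsv, root_posteriors, write_tree_newick)
from .genomescan import (clock_points_to_tsv, clock_statistics,
                         directionality_test, find_single_motifs,
                         hits_to_tsv, scan_proteome)
from .librarydesign import (PermutationFrame, apply_frame, enumerate_frames,
                            enumerate_library, library_to_fasta, mutagenize,
                            permute_construct, tandem_fuse)
from .seqrep import detect_internal_repeats, read_fasta, write_fasta

logger = logging.getLogger("propellerevo")

__all__ = ["PipelineConfig", "PipelineInputError", "run_reconstruct",
           "run_design", "run_scan_clock"]


class PipelineInputError(ValueError):
    """Bad or insufficient pipeline input (CLI exit code 2)."""


@dataclass
class PipelineConfig:
    """Configuration shared by the pipeline workflows.

    ``blade_shift`` is the circular rotation (residues) that moves the
    motif's C-terminal strand to the front, i.e. converts the Velcro frame
    to the intact-blade frame; it is structural knowledge supplied per
    family, not inferred from sequence.
    """

    input: str = ""
    output_dir: str = "propellerevo_out"
    model: str = "jtt"
    library_cutoff: float = 0.25
    identity_threshold: float = 0.5
    evalue: float = 1e-3
    blade_shift: int = 36
    polish_range: int = 2
    min_period: int = 20
    max_period: int = 60
    n_repeats: int = 5
    mutation_rate: float = 0.0
    n_clones: int = 0
    library_cap: int = 100_000
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.library_cutoff <= 1.0:
            raise ValueError("library_cutoff must lie in (0, 1]")
        if not 0.0 <= self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must lie in [0, 1]")
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")
        if self.polish_range < 0:
            raise ValueError("polish_range must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extra.update(extra)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_provenance(config: PipelineConfig, outdir: Path,
                      workflow: str, extras: dict | None = None) -> None:
    prov = {"workflow": workflow, "config": asdict(config),
            "config_hash": config.config_hash(), "seed": config.seed,
            "version": __version__}
    if extras:
        prov.update(extras)
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2))


def run_reconstruct(config: PipelineConfig
                    ) -> tuple[AncestralPosterior, dict]:
    """Repeat detection -> motif splitting -> alignment -> tree -> root
    posteriors, with all intermediate artefacts written to the output
    directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        records = read_fasta(config.input)
    except (ValueError, OSError) as exc:
        raise PipelineInputError(str(exc)) from exc
    motifs, labels = [], []
    for rec in records:
        ann = detect_internal_repeats(rec, config.min_period,
                                      config.max_period)
        if ann.motif_set is None:
            logger.info("%s: no internal repeats detected", rec.id)
            continue
        for j, motif in enumerate(ann.motif_set.motifs):
            motifs.append(motif)
            labels.append(f"{rec.id}_m{j + 1}")
    if len(motifs) < 2:
        raise PipelineInputError(
            "no detectable tandem repeats in the input; ancestral "
            "inference needs at least two motifs")
    alignment = align_motifs(motifs, labels)
    tree = build_tree(alignment, config.model)
    posterior = root_posteriors(alignment, tree, config.model)
    posterior_to_tsv(posterior, outdir / "posterior.tsv")
    write_fasta([("MPA", posterior.mpa)], outdir / "mpa.fasta")
    write_tree_newick(tree, outdir / "tree.nwk")
    _write_provenance(config, outdir, "reconstruct",
                      {"n_motifs": len(motifs),
                       "n_positions": posterior.n_positions})
    outputs = {"posterior": outdir / "posterior.tsv",
               "mpa": outdir / "mpa.fasta", "tree": outdir / "tree.nwk"}
    return posterior, outputs


def run_design(config: PipelineConfig, posterior: AncestralPosterior) -> dict:
    """Library enumeration plus the fusion/permutation construct
    trajectory (single motif -> 5-repeat blade fusion -> 6-repeat
    intermediate -> 5-repeat Velcro)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    mpa = posterior.mpa
    frames = enumerate_frames(len(mpa), config.blade_shift,
                              config.polish_range)
    library = enumerate_library(posterior, config.library_cutoff, frames,
                                config.blade_shift)
    result = {"n_variants": library.n_variants,
              "n_substitutions": library.n_substitutions,
              "n_frames": len(frames)}
    if library.n_variants <= config.library_cap:
        library_to_fasta(library, outdir / "library.fasta",
                         outdir / "library_manifest.tsv",
                         max_variants=config.library_cap)
    else:
        rng = np.random.default_rng(config.seed)
        keep = set(rng.choice(library.n_variants,
                              size=config.library_cap, replace=False))
        sample = [(f"{name}|v{i + 1}", seq)
                  for i, (name, seq) in enumerate(library.variants())
                  if i in keep]
        write_fasta(sample, outdir / "library_sample.fasta")
        logger.warning("library of %d variants exceeds cap %d; "
                       "wrote a seeded sample", library.n_variants,
                       config.library_cap)
        result["sampled"] = True
    b_frame = PermutationFrame("B")
    anc1b = apply_frame(mpa, b_frame, config.blade_shift)
    fusion = tandem_fuse(anc1b, config.n_repeats, b_frame,
                         name=f"Anc_{config.n_repeats}B")
    velcro = permute_construct(fusion, PermutationFrame("V"),
                               config.blade_shift)
    constructs = [("Anc_1B", anc1b), (fusion.name, fusion.protein),
                  (velcro.intermediate.name.replace("->x", "_x"),
                   velcro.intermediate.protein),
                  (velcro.name, velcro.protein)]
    write_fasta(constructs, outdir / "constructs.fasta")
    if config.mutation_rate > 0 and config.n_clones > 0:
        clones = mutagenize(anc1b, config.mutation_rate, config.n_clones,
                            config.seed)
        write_fasta([(f"Anc_1B_ep{i + 1}", c)
                     for i, c in enumerate(clones)],
                    outdir / "mutants.fasta")
        result["n_clones"] = len(clones)
    _write_provenance(config, outdir, "design", result)
    return result


def run_scan_clock(config: PipelineConfig) -> dict:
    """Proteome repeat scan -> single-motif homology search -> clock
    statistics and directionality test."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        proteome = read_fasta(config.input)
    except (ValueError, OSError) as exc:
        raise PipelineInputError(str(exc)) from exc
    propellers = scan_proteome(proteome, config.identity_threshold,
                               config.min_period, config.max_period)
    result: dict = {"n_proteins": len(proteome),
                    "n_propellers": len(propellers)}
    if not propellers:
        logger.warning("no internally repetitive propellers above the "
                       "identity threshold; clock analysis skipped")
        result["diagnostic"] = "no propellers detected"
        _write_provenance(config, outdir, "scan_clock", result)
        return result
    from .seqrep import annotations_to_tsv
    annotations_to_tsv(propellers, outdir / "propellers.tsv")
    all_hits = []
    for ann in propellers:
        all_hits.extend(find_single_motifs(ann, proteome, config.evalue,
                                           config.min_period,
                                           config.max_period))
    hits_to_tsv(all_hits, outdir / "hits.tsv")
    result["n_hits"] = len(all_hits)
    if not all_hits:
        logger.warning("no single-motif homologs at e < %g; clock skipped",
                       config.evalue)
        result["diagnostic"] = "no single-motif hits"
        _write_provenance(config, outdir, "scan_clock", result)
        return result
    best = min(all_hits, key=lambda h: h.evalue)
    single = next(r for r in proteome if r.id == best.subject_id)
    points, summary = clock_statistics(propellers, single)
    clock_points_to_tsv(points, outdir / "clock_points.tsv")
    report = directionality_test(points, seed=config.seed) \
        if len(points) >= 3 else {"flag": "insufficient points"}
    summary["single_motif_id"] = single.id
    summary["directionality"] = report
    (outdir / "clock_summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
    result.update(summary)
    _write_provenance(config, outdir, "scan_clock",
                      {"n_hits": len(all_hits),
                       "single_motif_id": single.id})
    return result
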