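"""Construct design from an ancestral posterior: combinatorial substitution
libraries, circular permutation frames, tandem fusions, frame
interconversion and error-prone mutant libraries.

A repeat motif can be expressed in two topologies: the Velcro frame (V), in
which the C-terminal strand closes the N-terminal blade as in the extant
lectin, and the intact-blade frame (B), a circular permutation that places
the motif boundary at a structural blade boundary.  Because the exact blade
boundary is known only structurally, B frames carry an "end polishing"
offset of up to +/-2 residues around the canonical rotation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .ancestral import AncestralPosterior
from .substmodel import AA_INDEX, AMINO_ACIDS

__all__ = [
    "PermutationFrame", "VariantLibrary", "ConstructSpec",
    "enumerate_frames", "apply_frame", "enumerate_library", "tandem_fuse",
    "permute_construct", "mutagenize", "library_to_fasta",
]


@dataclass(frozen=True)
class PermutationFrame:
    """A motif reading frame: ``V`` (Velcro, identity) or ``B`` (intact
    blade, circular rotation) with an end-polishing offset in [-2, +2]."""

    topology: str
    polish_offset: int = 0

    def __post_init__(self):
        if self.topology not in ("V", "B"):
            raise ValueError("topology must be 'V' or 'B'")
        if self.topology == "V" and self.polish_offset != 0:
            raise ValueError("V frame takes no polish offset")

    @property
    def tag(self) -> str:
        if self.topology == "V":
            return "V"
        off = self.polish_offset
        return f"B{off:+d}" if off else "B"


def enumerate_frames(motif_length: int, blade_shift: int,
                     polish_range: int = 2) -> list[PermutationFrame]:
    """All permutation frames for a motif: the Velcro frame plus one blade
    frame per polishing offset in ``[-polish_range, +polish_range]``.

    With the default polishing range of 2 this yields exactly six frames.
    """
    if polish_range < 0:
        raise ValueError("polish_range must be non-negative")
    if motif_length <= 2 * polish_range:
        raise ValueError("motif shorter than twice the polishing range")
    frames = [PermutationFrame("V")]
    frames += [PermutationFrame("B", off)
               for off in range(-polish_range, polish_range + 1)]
    for f in frames[1:]:
        if abs(blade_shift + f.polish_offset) >= motif_length:
            raise ValueError("blade shift out of range for motif length")
    return frames


def apply_frame(motif: str, frame: PermutationFrame,
                blade_shift: int) -> str:
    """Express ``motif`` in ``frame``: identity for V, circular left
    rotation by ``blade_shift + polish_offset`` for B.  Length-preserving."""
    if frame.topology == "V":
        return motif
    shift = blade_shift + frame.polish_offset
    if abs(shift) >= len(motif):
        raise ValueError(
            f"rotation {shift} out of range for motif length {len(motif)}")
    shift %= len(motif)
    return motif[shift:] + motif[:shift]


@dataclass
class VariantLibrary:
    """A combinatorial substitution library over a base (MPA) sequence.

    ``alternatives`` maps 0-based positions to the sorted tuple of non-MPA
    residues whose posterior probability exceeded the cutoff; the library
    enumerates every combination of base/alternative states in every frame.
    """

    base: str
    alternatives: dict[int, tuple[str, ...]]
    frames: list[PermutationFrame]
    blade_shift: int
    cutoff: float

    @property
    def n_variants(self) -> int:
        n = len(self.frames)
        for alts in self.alternatives.values():
            n *= 1 + len(alts)
        return n

    @property
    def n_substitutions(self) -> int:
        return sum(len(a) for a in self.alternatives.values())

    def variants(self) -> Iterator[tuple[str, str]]:
        """Yield (name, sequence) deterministically: frames in their listed
        order (V first, then B by offset); positions ascending; residues with
        the base state first then alphabetically."""
        positions = sorted(self.alternatives)
        choices = [(None,) + self.alternatives[p] for p in positions]
        for combo in itertools.product(*choices):
            seq = list(self.base)
            subs = []
            for p, res in zip(positions, combo):
                if res is not None:
                    subs.append(f"{self.base[p]}{p + 1}{res}")
                    seq[p] = res
            motif = "".join(seq)
            sub_tag = "+".join(subs)
            for frame in self.frames:
                name = f"Anc_1{frame.tag}"
                if sub_tag:
                    name += "+" + sub_tag
                yield name, apply_frame(motif, frame, self.blade_shift)


def enumerate_library(posterior: AncestralPosterior, cutoff: float,
                      frames: list[PermutationFrame],
                      blade_shift: int = 0) -> VariantLibrary:
    """Build the combinatorial library of alternative ancestral states whose
    posterior probability strictly exceeds ``cutoff`` (the MPA residue is
    always the base state and never listed as an alternative)."""
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must lie in (0, 1]")
    base = posterior.mpa
    alternatives: dict[int, tuple[str, ...]] = {}
    for i in range(posterior.n_positions):
        alts = [AMINO_ACIDS[k] for k in range(20)
                if posterior.posterior[i, k] > cutoff
                and AMINO_ACIDS[k] != base[i]]
        if alts:
            alternatives[i] = tuple(sorted(alts))
    return VariantLibrary(base=base, alternatives=alternatives,
                          frames=list(frames), blade_shift=blade_shift,
                          cutoff=cutoff)


@dataclass
class ConstructSpec:
    """A designed protein: one or more motif repeats in a given frame."""

    name: str
    motifs: list[str]
    frame: PermutationFrame
    intermediate: "ConstructSpec | None" = field(default=None, repr=False)

    @property
    def n_repeats(self) -> int:
        return len(self.motifs)

    @property
    def protein(self) -> str:
        return "".join(self.motifs)

    def __len__(self) -> int:
        return len(self.protein)


def tandem_fuse(motif: str, n: int, frame: PermutationFrame | None = None,
                name: str | None = None) -> ConstructSpec:
    """Head-to-tail fusion of ``n`` identical motif copies, no linker."""
    if n < 1:
        raise ValueError("n must be >= 1")
    frame = frame or PermutationFrame("V")
    if name is None:
        name = f"Anc_{n}{frame.tag}"
    return ConstructSpec(name=name, motifs=[motif] * n, frame=frame)


def permute_construct(spec: ConstructSpec, target_frame: PermutationFrame,
                      blade_shift: int) -> ConstructSpec:
    """Interconvert a tandem fusion between frames via motif expansion.

    Models the genetic mechanism: one motif copy is appended (the n+1-repeat
    intermediate), then new start/stop positions truncate back to n repeats
    read in the target frame.  The emitted repeat is the circular rotation
    of the original motif by the difference of frame shifts; the
    intermediate is recorded on the returned spec.
    """
    if len(set(spec.motifs)) != 1:
        raise ValueError("frame interconversion requires identical repeats")
    if target_frame == spec.frame:
        warnings.warn("target frame equals current frame; no-op")
        return spec
    motif = spec.motifs[0]

    def _shift(frame: PermutationFrame) -> int:
        if frame.topology == "V":
            return 0
        return blade_shift + frame.polish_offset

    intermediate = ConstructSpec(
        name=f"{spec.name}->x{spec.n_repeats + 1}",
        motifs=[motif] * (spec.n_repeats + 1), frame=spec.frame)
    delta = (_shift(target_frame) - _shift(spec.frame)) % len(motif)
    new_motif = motif[delta:] + motif[:delta]
    return ConstructSpec(
        name=f"Anc_{spec.n_repeats}{target_frame.tag}",
        motifs=[new_motif] * spec.n_repeats, frame=target_frame,
        intermediate=intermediate)


def mutagenize(seq: str, rate: float, n_clones: int,
               seed: int) -> list[str]:
    """Error-prone mutant library at the protein level.

    Each clone receives a Poisson(``rate``) number of substitutions at
    uniformly drawn distinct positions; the substituted residue is uniform
    over the 19 non-identical amino acids.  Reproducible under ``seed``.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(seq)
    clones = []
    counts = rng.poisson(rate, size=n_clones)
    for k in counts:
        k = min(int(k), n)
        if k == 0:
            clones.append(seq)
            continue
        positions = rng.choice(n, size=k, replace=False)
        s = list(seq)
        for p in positions:
            current = AA_INDEX[s[p]]
            r = int(rng.integers(19))
            if r >= current:
                r += 1
            s[p] = AMINO_ACIDS[r]
        clones.append("".join(s))
    return clones


def library_to_fasta(library: VariantLibrary, fasta_path: str | Path,
                     manifest_path: str | Path | None = None,
                     max_variants: int = 100_000) -> pd.DataFrame:
    """Write every variant to FASTA plus a TSV manifest.

    Refuses enumeration above ``max_variants`` (the designed libraries are
    three orders of magnitude smaller)."""
    from .seqrep import write_fasta
    if library.n_variants > max_variants:
        raise ValueError(
            f"library of {library.n_variants} variants exceeds the "
            f"enumeration cap {max_variants}")
    records = []
    rows = []
    for i, (name, seq) in enumerate(library.variants()):
        uid = f"{name}|v{i + 1}"
        records.append((uid, seq))
        rows.append({"variant": uid, "length": len(seq)})
    write_fasta(records, fasta_path)
    df = pd.DataFrame(rows)
    if manifest_path is not None:
        df.to_csv(manifest_path, sep="\t", index=False)
    return df
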