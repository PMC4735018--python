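"""Ground-truthed synthetic data: duplication-fusion-divergence sequence
families, decoy proteomes and noisy biophysical curves.

The family generator implements the duplication-fusion-divergence model
directly: a single ancestor motif is drawn from the substitution model's
stationary distribution; each propeller is born by tandem-fusing k copies
and every copy then diverges independently for the propeller's age
(substitutions/site).  A single-motif protein descends from the same
ancestor.  Because the generative truth (boundaries, ages, tree) is
recorded, every downstream stage -- repeat detection, ancestral inference,
clock statistics, curve fitting -- can be scored against it.

Scenario "A" (the default) is the motif-first history the clock analysis
assumes.  Scenario "B" models co-option: the "single motif" is a recent
copy of one repeat of an extant propeller, which makes that repeat
disproportionately similar to it -- the signature the directionality test
must detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .foldbiophys import (CalibrationCurve, DenaturationDataset, melt_signal,
                          three_state_signal, two_state_signal)
from .seqrep import SequenceRecord
from .substmodel import get_model

__all__ = ["SimFamily", "CurveSpec", "simulate_family", "simulate_proteome",
           "simulate_curve", "two_state_spec", "three_state_spec"]

# Canonical unfolding-curve conditions: a 0-6 M GdmCl gradient sampled every
# 0.05 M with Gaussian noise of 1% of the signal range.  Baselines mimic
# tryptophan-fluorescence unfolding (bright native state, dim denatured
# state, intermediate signal distinctly below the baseline midpoint so the
# two inflections are resolved).
TWO_STATE_DEFAULTS = dict(cm=2.0, m=2.0, a_n=1.0, b_n=-0.01,
                          a_d=0.2, b_d=0.005)
THREE_STATE_DEFAULTS = dict(cm1=2.0, m1=6.0, m2=6.0, a_n=1.0, b_n=-0.02,
                            a_i=0.45, a_d=0.15, b_d=0.01)
DEFAULT_NOISE_SD = 0.0085          # 1% of the ~0.85 AU signal range
DEFAULT_N_POINTS = 121


def two_state_spec(cm: float = 2.0, m: float = 2.0, seed: int = 0,
                   noise_sd: float = DEFAULT_NOISE_SD,
                   n_points: int = DEFAULT_N_POINTS) -> "CurveSpec":
    """Canonical two-state chemical-denaturation curve spec."""
    params = dict(TWO_STATE_DEFAULTS, cm=cm, m=m)
    return CurveSpec("two_state", params, noise_sd=noise_sd,
                     n_points=n_points, seed=seed)


def three_state_spec(delta_cm: float, cm1: float = 2.0, seed: int = 0,
                     noise_sd: float = DEFAULT_NOISE_SD,
                     n_points: int = DEFAULT_N_POINTS) -> "CurveSpec":
    """Canonical three-state curve spec with inter-inflection interval
    ``delta_cm`` (M GdmCl)."""
    params = dict(THREE_STATE_DEFAULTS, cm1=cm1, cm2=cm1 + delta_cm)
    return CurveSpec("three_state", params, noise_sd=noise_sd,
                     n_points=n_points, seed=seed)


@dataclass
class SimFamily:
    """A simulated propeller family with its full generative truth."""

    ancestor_motif: str
    propellers: list[SequenceRecord]
    true_boundaries: dict[str, list[tuple[int, int]]]
    true_motifs: dict[str, list[str]]
    ages: dict[str, float]
    motif_counts: dict[str, int]
    single_motif_protein: SequenceRecord
    single_motif_region: tuple[int, int]
    true_tree: TreeNode
    scenario: str = "A"
    stem_fraction: float = 0.25
    co_option_donor: str | None = None
    events: list[tuple[str, float, int]] = field(default_factory=list)


def simulate_family(ancestor_length: int = 47,
                    n_propellers: int = 11,
                    motif_count_range: tuple[int, int] = (5, 7),
                    age_spread: tuple[float, float] = (0.1, 1.5),
                    model: str = "jtt",
                    seed: int = 0,
                    scenario: str = "A",
                    stem_fraction: float = 0.25,
                    single_motif_age: float = 0.1,
                    flank_length: int = 17,
                    co_option_age: float = 0.05,
                    co_option_max_donor_age: float = 0.35) -> SimFamily:
    """Simulate a family of propellers descending from one duplicated-fused
    motif.

    Ages are drawn log-uniformly over ``age_spread`` so the clock plot is
    populated evenly across divergence.  Each propeller consists of a stem
    branch (``stem_fraction`` x age, shared by its motifs, which makes the
    motifs of one protein monophyletic) followed by independent per-motif
    branches of length age.  The single-motif protein carries the motif
    flanked by ``flank_length`` stationary-composition residues on each
    side (47 + 2 x 17 = 81 residues by default).
    """
    if age_spread[0] <= 0 or age_spread[1] < age_spread[0]:
        raise ValueError("ages must be positive and ordered")
    m = get_model(model)
    rng = np.random.default_rng(seed)
    ancestor = m.stationary_sample(ancestor_length, rng)
    lo, hi = age_spread
    if n_propellers == 1 or hi == lo:
        ages_arr = np.full(n_propellers, lo)
    else:
        ages_arr = np.exp(rng.uniform(np.log(lo), np.log(hi),
                                      size=n_propellers))
        ages_arr = np.sort(ages_arr)
    propellers = []
    true_boundaries: dict[str, list[tuple[int, int]]] = {}
    true_motifs: dict[str, list[str]] = {}
    ages: dict[str, float] = {}
    motif_counts: dict[str, int] = {}
    events = []
    subtrees = []
    for i in range(n_propellers):
        pid = f"prop{i + 1:02d}"
        k = int(rng.integers(motif_count_range[0], motif_count_range[1] + 1))
        age = float(ages_arr[i])
        stem = stem_fraction * age
        birth_motif = m.evolve(ancestor, stem, rng)
        motifs = [m.evolve(birth_motif, age, rng) for _ in range(k)]
        seq = "".join(motifs)
        propellers.append(SequenceRecord(pid, seq, source="simulated"))
        true_boundaries[pid] = [(j * ancestor_length,
                                 (j + 1) * ancestor_length)
                                for j in range(k)]
        true_motifs[pid] = motifs
        ages[pid] = age
        motif_counts[pid] = k
        events.append((pid, age, k))
        children = ",".join(f"{pid}_m{j + 1}:{age}" for j in range(k))
        subtrees.append(f"({children}):{stem}")
    donor = None
    if scenario == "A":
        single_core = m.evolve(ancestor, single_motif_age, rng)
        subtrees.append(f"single:{single_motif_age}")
    elif scenario == "B":
        # co-option: the single motif is a recent copy of one repeat of an
        # extant propeller.  The donor is the oldest propeller that a
        # >=50%-internal-identity scan would still retain, so the
        # asymmetry of this history is visible among detected propellers.
        candidates = [p.id for p in propellers
                      if ages[p.id] <= co_option_max_donor_age]
        donor = candidates[-1] if candidates else propellers[0].id
        single_core = m.evolve(true_motifs[donor][0], co_option_age, rng)
    else:
        raise ValueError("scenario must be 'A' or 'B'")
    flanks = (m.stationary_sample(flank_length, rng),
              m.stationary_sample(flank_length, rng))
    single = SequenceRecord("single", flanks[0] + single_core + flanks[1],
                            source="simulated")
    newick = "(" + ",".join(subtrees) + ");"
    tree = TreeNode.read([newick])
    return SimFamily(
        ancestor_motif=ancestor, propellers=propellers,
        true_boundaries=true_boundaries, true_motifs=true_motifs,
        ages=ages, motif_counts=motif_counts,
        single_motif_protein=single,
        single_motif_region=(flank_length, flank_length + ancestor_length),
        true_tree=tree, scenario=scenario, stem_fraction=stem_fraction,
        co_option_donor=donor, events=events)


def simulate_proteome(family: SimFamily, n_decoys: int,
                      decoy_length_range: tuple[int, int] = (100, 400),
                      seed: int = 0
                      ) -> tuple[list[SequenceRecord], dict]:
    """Embed the family's sequences among composition-matched decoys.

    Decoys are i.i.d. draws from the aggregate residue composition of the
    family (so they carry no repeat structure); planted sequences are
    interleaved at seeded positions.  Returns the proteome and a truth
    manifest mapping planted ids to their roles.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be non-negative")
    rng = np.random.default_rng(seed)
    planted = list(family.propellers) + [family.single_motif_protein]
    pool = "".join(rec.residues for rec in planted)
    letters, counts = np.unique(list(pool), return_counts=True)
    freqs = counts / counts.sum()
    records: list[SequenceRecord] = []
    for i in range(n_decoys):
        n = int(rng.integers(decoy_length_range[0],
                             decoy_length_range[1] + 1))
        seq = "".join(rng.choice(letters, size=n, p=freqs))
        records.append(SequenceRecord(f"decoy{i + 1:04d}", seq,
                                      source="decoy"))
    positions = sorted(rng.choice(len(records) + len(planted),
                                  size=len(planted), replace=False))
    for pos, rec in zip(positions, planted):
        records.insert(min(pos, len(records)), rec)
    manifest = {
        "propellers": {p.id: {"n_motifs": family.motif_counts[p.id],
                              "age": family.ages[p.id]}
                       for p in family.propellers},
        "single_motif": family.single_motif_protein.id,
        "scenario": family.scenario,
        "n_decoys": n_decoys,
    }
    return records, manifest


@dataclass
class CurveSpec:
    """Specification of a synthetic biophysical curve."""

    model: str                     # two_state | three_state | melt | calibration
    params: dict
    noise_sd: float = 0.0
    n_points: int = 61
    x_range: tuple[float, float] = (0.0, 6.0)
    seed: int = 0
    log_spaced: bool = False

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_points < 10:
            raise ValueError("need at least 10 points")


_MODEL_FUNCS = {
    "two_state": (two_state_signal,
                  ["cm", "m", "a_n", "b_n", "a_d", "b_d"]),
    "three_state": (three_state_signal,
                    ["cm1", "cm2", "m1", "m2", "a_n", "b_n", "a_i",
                     "a_d", "b_d"]),
    "melt": (melt_signal, ["tm", "width", "a_n", "b_n", "a_d", "b_d"]),
}


def simulate_curve(spec: CurveSpec):
    """Evaluate the specified model exactly and add Gaussian noise.

    Returns a :class:`DenaturationDataset` for unfolding/melt models, or an
    (x, y) pair for the calibration model.  Byte-reproducible under the
    spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.x_range
    if spec.log_spaced:
        x = np.geomspace(lo, hi, spec.n_points)
    else:
        x = np.linspace(lo, hi, spec.n_points)
    if spec.model == "calibration":
        curve = CalibrationCurve(**spec.params)
        y = curve.predict(x)
        y = y + rng.normal(0.0, spec.noise_sd, size=len(x))
        return x, y
    if spec.model not in _MODEL_FUNCS:
        raise ValueError(f"unknown curve model {spec.model!r}")
    func, names = _MODEL_FUNCS[spec.model]
    missing = set(names) - set(spec.params)
    if missing:
        raise ValueError(f"missing parameters {sorted(missing)}")
    y = func(x, *[spec.params[n] for n in names])
    y = y + rng.normal(0.0, spec.noise_sd, size=len(x))
    return DenaturationDataset(x=x, y=y)
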