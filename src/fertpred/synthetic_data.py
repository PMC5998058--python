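"""Synthetic labeled protein pools with controllable class signal.

Real training data for fertility-protein classification comes from curated
database searches; this module emulates such pools so every other component
can be exercised and validated without downloads.  The planted signal is
compositional (class-specific residue-frequency enrichment, optionally with
short planted motifs), because the descriptor families are composition and
order statistics of exactly this kind.

The default benchmark suite gives all three fertility classes a shared
serine/isoleucine enrichment (the "general" signature a feature selector
should recover) plus one class-specific extra each: additional serine for
oogenesis, additional isoleucine for spermatogenesis, and planted
isoleucine-alanine repeats for embryogenesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tables import AMINO_ACIDS
from .sequence_io import ProteinSequence

__all__ = [
    "GeneratorSpec",
    "LabeledPool",
    "generate_pool",
    "generate_benchmark_suite",
    "background_frequencies",
    "bias_frequencies",
]

#: Approximate background residue frequencies of curated protein databases.
_BACKGROUND = {
    "A": 8.26, "R": 5.53, "N": 4.06, "D": 5.46, "C": 1.37, "Q": 3.93,
    "E": 6.72, "G": 7.08, "H": 2.27, "I": 5.91, "L": 9.65, "K": 5.80,
    "M": 2.41, "F": 3.86, "P": 4.74, "S": 6.63, "T": 5.35, "W": 1.10,
    "Y": 2.92, "V": 6.86,
}


@dataclass
class LabeledPool:
    """A class label plus its member sequences (unique ids)."""

    class_label: str
    sequences: list[ProteinSequence]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate sequence ids in pool {self.class_label!r}")

    def __len__(self) -> int:
        return len(self.sequences)


def background_frequencies() -> np.ndarray:
    """Background residue frequencies, normalized, in alphabet order."""
    v = np.array([_BACKGROUND[aa] for aa in AMINO_ACIDS])
    return v / v.sum()


def bias_frequencies(base: np.ndarray, multipliers: dict[str, float]) -> np.ndarray:
    """Multiply selected residue frequencies and renormalize to the simplex."""
    v = base.copy()
    for aa, m in multipliers.items():
        v[AMINO_ACIDS.index(aa)] *= m
    return v / v.sum()


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic pool.

    ``class_composition_bias`` maps class label -> residue-frequency vector
    (a simplex over the 20 residues, alphabet order); ``motif_plants`` lists
    ``(class_label, motif, insertion_probability)`` triples.  Lengths are
    drawn uniformly from ``length_range``, which must sit strictly inside
    the validated (60, 6000) window.
    """

    n_per_class: int = 60
    length_range: tuple[int, int] = (80, 200)
    class_composition_bias: dict[str, np.ndarray] = field(default_factory=dict)
    motif_plants: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (60 < lo <= hi < 6000):
            raise ValueError("length_range must lie strictly inside (60, 6000)")
        for label, v in self.class_composition_bias.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (20,) or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-8:
                raise ValueError(f"bias for {label!r} is not a 20-simplex")


def generate_pool(spec: GeneratorSpec, class_label: str) -> LabeledPool:
    """Draw one labeled pool of i.i.d. biased-composition sequences.

    Deterministic for a given (spec.seed, class_label) pair: each class has
    its own RNG stream, so adding a class never reshuffles another's draw.
    """
    freqs = spec.class_composition_bias.get(class_label)
    if freqs is None:
        freqs = background_frequencies()
    freqs = np.asarray(freqs, dtype=float)
    class_key = int.from_bytes(class_label.encode(), "little") % (2**31)
    rng = np.random.default_rng([spec.seed, class_key])
    motifs = [(m, p) for lbl, m, p in spec.motif_plants if lbl == class_label]
    lo, hi = spec.length_range
    alphabet = np.array(list(AMINO_ACIDS))
    seqs = []
    for i in range(spec.n_per_class):
        L = int(rng.integers(lo, hi + 1))
        residues = "".join(rng.choice(alphabet, size=L, p=freqs))
        for motif, p in motifs:
            if rng.random() < p and len(motif) < L:
                pos = int(rng.integers(0, L - len(motif) + 1))
                residues = residues[:pos] + motif + residues[pos + len(motif):]
        seqs.append(ProteinSequence(id=f"{class_label}_{i:05d}", residues=residues))
    return LabeledPool(class_label=class_label, sequences=seqs)


#: Labels of the three fertility classes, alphabetical.
FERTILITY_CLASSES = ("embryogenesis", "oogenesis", "spermatogenesis")


def generate_benchmark_suite(
    seed: int,
    n_per_class: int = 100,
    n_negative: int = 1600,
    length_range: tuple[int, int] = (80, 200),
    effect_scale: float = 1.0,
) -> tuple[dict[str, LabeledPool], dict]:
    """Generate the default study pools: 3 positive classes + negatives.

    Effect sizes (fixed once, documented): every fertility class carries the
    shared signature S x2.0, I x2.0 over background; oogenesis additionally
    S x1.5, spermatogenesis additionally I x1.5, and embryogenesis carries
    planted "IAIAIA" repeats (insertion probability 0.9).  ``effect_scale``
    interpolates the multipliers toward 1 (0 = null suite with no class
    signal, for permutation-style controls).

    Returns the pools keyed by label (three classes + ``negative``) and a
    truth dictionary recording biases, motifs and the planted feature names.
    """
    base = background_frequencies()

    def scaled(mult: dict[str, float]) -> dict[str, float]:
        return {aa: 1.0 + effect_scale * (m - 1.0) for aa, m in mult.items()}

    biases = {
        "oogenesis": bias_frequencies(base, scaled({"S": 2.0 * 1.5, "I": 2.0})),
        "spermatogenesis": bias_frequencies(base, scaled({"S": 2.0, "I": 2.0 * 1.5})),
        "embryogenesis": bias_frequencies(base, scaled({"S": 2.0, "I": 2.0})),
        "negative": base,
    }
    motif_p = 0.9 * effect_scale
    spec = GeneratorSpec(
        n_per_class=n_per_class,
        length_range=length_range,
        class_composition_bias=biases,
        motif_plants=[("embryogenesis", "IAIAIA", motif_p)],
        seed=seed,
    )
    pools = {label: generate_pool(spec, label) for label in FERTILITY_CLASSES}
    neg_spec = GeneratorSpec(
        n_per_class=n_negative,
        length_range=length_range,
        class_composition_bias=biases,
        seed=seed,
    )
    pools["negative"] = generate_pool(neg_spec, "negative")
    truth = {
        "seed": seed,
        "effect_scale": effect_scale,
        "biases": {k: v.tolist() for k, v in biases.items()},
        "motifs": [("embryogenesis", "IAIAIA", motif_p)],
        "planted_features": ["S", "I"],
        "n_per_class": n_per_class,
        "n_negative": n_negative,
        "length_range": list(length_range),
    }
    return pools, truth
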