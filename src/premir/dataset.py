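"""Labelled dataset assembly: filtering, 75/25 split, synthetic fixtures.

The filter policy mirrors the bounds observed across real insect precursor
collections: length strictly below 250 nt (the longest known insect precursor
is 222 nt), MFE within [-180, -5] kcal/mol and GC content within [10, 85] %.

``generate_fixtures`` builds a deterministic synthetic study set: positives
are constructed stem-loops (15-40 complementary pairs with ~10% G·U wobble, a
3-10 nt hairpin loop, short flanking tails) with a consistent dot-bracket and
a surrogate stacking energy; negatives are dinucleotide-preserving shuffles of
positives plus random weakly structured sequences, folded by the deterministic
stacking backend. It emulates the hairpin-vs-non-hairpin contrast, not the
thermodynamics or the genomic base composition of real precursors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import dinucleotide_shuffle, gc_percent
from .structure_io import (
    CANONICAL_PAIRS,
    RnaRecord,
    SecondaryStructure,
    StackingBackend,
    annotate_motifs,
)

__all__ = [
    "FilterPolicy",
    "FilterResult",
    "apply_filters",
    "split_dataset",
    "generate_fixtures",
]


@dataclass(frozen=True)
class FilterPolicy:
    """Keep criteria: length < max_length, MFE and GC inside closed windows."""

    max_length: int = 250
    mfe_window: tuple[float, float] = (-180.0, -5.0)
    gc_window: tuple[float, float] = (10.0, 85.0)

    def __post_init__(self) -> None:
        if self.mfe_window[0] > self.mfe_window[1]:
            raise ValueError("mfe_window must be (low, high)")
        if self.gc_window[0] > self.gc_window[1]:
            raise ValueError("gc_window must be (low, high)")


@dataclass
class FilterResult:
    kept: list[tuple[RnaRecord, SecondaryStructure]]
    rejected: list[tuple[RnaRecord, str]] = field(default_factory=list)


def apply_filters(
    pairs, policy: FilterPolicy = FilterPolicy()
) -> FilterResult:
    """Partition (record, structure) pairs into kept and rejected-with-reason.

    A record is kept iff length < ``max_length`` AND MFE within
    ``mfe_window`` (inclusive) AND GC%% within ``gc_window`` (inclusive).
    Each rejection carries the first failing rule, checked in that order.
    """
    result = FilterResult(kept=[])
    for rec, st in pairs:
        if len(rec) >= policy.max_length:
            result.rejected.append((rec, "max_length"))
        elif not policy.mfe_window[0] <= st.mfe <= policy.mfe_window[1]:
            result.rejected.append((rec, "mfe_window"))
        elif not policy.gc_window[0] <= gc_percent(rec.sequence) <= policy.gc_window[1]:
            result.rejected.append((rec, "gc_window"))
        else:
            result.kept.append((rec, st))
    return result


def split_dataset(
    table: pd.DataFrame,
    train_fraction: float = 0.75,
    seed: int = 0,
    label_col: str = "label",
) -> pd.DataFrame:
    """Assign a stratified train/test split to a labelled feature table.

    Adds a ``split`` column with values 'train'/'test'; proportions per class
    are within one row of ``train_fraction``. Deterministic under ``seed``.
    """
    from sklearn.model_selection import train_test_split

    if len(table) < 4:
        raise ValueError("split needs at least 4 rows")
    labels = table[label_col]
    if labels.nunique() < 2:
        raise ValueError("split needs both classes present")
    idx_train, idx_test = train_test_split(
        table.index.to_numpy(),
        train_size=train_fraction,
        stratify=labels.to_numpy(),
        random_state=seed,
    )
    out = table.copy()
    out["split"] = "test"
    out.loc[idx_train, "split"] = "train"
    return out


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _sample_hairpin(
    rng: np.random.Generator,
    stem_range: tuple[int, int] = (15, 40),
    loop_range: tuple[int, int] = (3, 10),
    tail_range: tuple[int, int] = (2, 8),
    wobble_rate: float = 0.1,
) -> tuple[str, str]:
    """One synthetic stem-loop: returns (sequence, dot-bracket)."""
    n_stem = int(rng.integers(stem_range[0], stem_range[1] + 1))
    n_loop = int(rng.integers(loop_range[0], loop_range[1] + 1))
    tail5 = int(rng.integers(tail_range[0], tail_range[1] + 1))
    tail3 = int(rng.integers(tail_range[0], tail_range[1] + 1))
    nts = np.array(list("ACGU"))
    five = "".join(rng.choice(nts, size=n_stem))
    three = []
    for ch in reversed(five):
        if ch in "GU" and rng.random() < wobble_rate:
            three.append("U" if ch == "G" else "G")  # G·U wobble partner
        else:
            three.append(_COMPLEMENT[ch])
    loop = "".join(rng.choice(nts, size=n_loop))
    t5 = "".join(rng.choice(nts, size=tail5))
    t3 = "".join(rng.choice(nts, size=tail3))
    seq = t5 + five + loop + "".join(three) + t3
    db = (
        "." * tail5 + "(" * n_stem + "." * n_loop + ")" * n_stem + "." * tail3
    )
    assert all(
        (a, b) in CANONICAL_PAIRS
        for a, b in zip(five, reversed("".join(three)))
    )
    return seq, db


def generate_fixtures(
    n_pos: int,
    n_neg: int,
    seed: int = 0,
    length_range: tuple[int, int] = (40, 110),
) -> list[tuple[RnaRecord, SecondaryStructure, int]]:
    """Deterministic synthetic study set of (record, structure, label) triples.

    Positives (label 1) are constructed stem-loops whose structure follows
    from the construction; their surrogate MFE is the stacking score of the
    deterministic backend (-2 kcal/mol per stacked pair, +3 per loop), which
    keeps every positive inside the default :class:`FilterPolicy` windows.
    Negatives (label 0) are an even mix of dinucleotide shuffles of fresh
    hairpins (composition-matched) and uniform random sequences, folded by
    :class:`StackingBackend`. ``length_range`` bounds the random negatives.
    """
    rng = np.random.default_rng(seed)
    backend = StackingBackend()
    out: list[tuple[RnaRecord, SecondaryStructure, int]] = []
    for i in range(n_pos):
        seq, db = _sample_hairpin(rng)
        st = annotate_motifs(SecondaryStructure(dotbracket=db))
        st.mfe = StackingBackend._surrogate_energy(st)
        st.pair_probs = _fixture_probs(st, backend.pair_confidence)
        out.append(
            (RnaRecord(id=f"pos_{i:04d}", sequence=seq, source="synthetic"), st, 1)
        )
    nts = np.array(list("ACGU"))
    for i in range(n_neg):
        if i % 2 == 0:
            seq, _ = _sample_hairpin(rng)
            seq = dinucleotide_shuffle(seq, rng)
        else:
            L = int(rng.integers(length_range[0], length_range[1] + 1))
            seq = "".join(rng.choice(nts, size=L))
        st = backend.fold(seq)
        st.pair_probs = _fixture_probs(st, backend.pair_confidence)
        out.append(
            (RnaRecord(id=f"neg_{i:04d}", sequence=seq, source="synthetic"), st, 0)
        )
    return out


def _fixture_probs(st: SecondaryStructure, confidence: float) -> np.ndarray:
    n = len(st)
    probs = np.zeros((n, n))
    for i, j in st.pair_table.items():
        if i < j:
            probs[i - 1, j - 1] = confidence
    return probs
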