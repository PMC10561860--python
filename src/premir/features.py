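"""The 93-feature descriptor for a (sequence, secondary structure) pair.

Feature groups (see :mod:`premir.manifest` for the exact ordering):

* **Triplet elements** — for each 3-nt window the local pairing pattern
  (with ')' rewritten to '(') is combined with the middle nucleotide into one
  of 32 bins; frequencies are counts over the L-2 windows.
* **Base composition** — %X = |X|/L*100 for each nucleotide, %XY over the
  L-1 overlapping dinucleotide windows, and the G+C / A+U pair compositions.
* **Structural / thermodynamic** — dG = MFE/L, dP = tot_bp/L,
  MFE1 = dG/%(G+C), MFE2 = dG/n_stems, MFE3 = dG/n_loops, MFE4 = dG/tot_bp,
  avg_bp = tot_bp/n_stems. Zero denominators yield 0 by convention so that
  degenerate (unfolded) inputs stay finite and classifiable.
* **Ensemble features** — from the base-pair probability matrix p_ij:
  Shannon entropy Q = -sum p_ij log2 p_ij, its normalization dQ = Q/L, the
  ensemble base-pair distance per nucleotide dD = sum p_ij (1 - p_ij) / L,
  and zD, the z-score of dD against M dinucleotide-preserving shuffles of the
  sequence refolded by the same backend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .manifest import (
    NUCLEOTIDES,
    TRIPLET_PATTERNS,
    FeatureManifest,
    default_manifest,
)
from .structure_io import (
    FoldingBackend,
    RnaRecord,
    SecondaryStructure,
    fold_with_probabilities,
)

__all__ = [
    "FeatureVector",
    "triplet_elements",
    "composition_features",
    "thermo_features",
    "entropy_features",
    "shuffle_z_score",
    "dinucleotide_shuffle",
    "featurize",
    "featurize_many",
    "fit_scaler",
    "apply_scaler",
]


@dataclass(frozen=True)
class FeatureVector:
    """An ordered 93-value descriptor tied to a manifest version."""

    record_id: str
    values: np.ndarray
    manifest_version: str
    scaled: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (93,):
            raise ValueError(f"feature vector must have 93 values, got {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"record {self.record_id!r}: non-finite feature values")

    def as_dict(self, manifest: FeatureManifest | None = None) -> dict[str, float]:
        manifest = manifest or default_manifest()
        return dict(zip(manifest.names, self.values.tolist()))


def _safe_div(num: float, den: float) -> float:
    """num/den with the 0-on-zero-denominator convention."""
    return num / den if den != 0 else 0.0


# ---------------------------------------------------------------------------
# Triplet elements
# ---------------------------------------------------------------------------


def triplet_elements(sequence: str, dotbracket: str) -> dict[str, float]:
    """Frequencies of the 32 (middle nucleotide x pairing pattern) bins.

    Every window of three adjacent positions contributes one count to the bin
    keyed by its middle nucleotide and its 3-character pattern after mapping
    ')' to '(' (both partners of a pair read as paired). Counts are divided
    by the number of windows, L - 2.
    """
    L = len(sequence)
    if L < 3:
        raise ValueError(f"triplet elements need L >= 3, got L = {L}")
    if len(dotbracket) != L:
        raise ValueError("sequence/structure length mismatch")
    flat = dotbracket.replace(")", "(")
    counts = {f"{nt}{pat}": 0 for nt in NUCLEOTIDES for pat in TRIPLET_PATTERNS}
    for i in range(L - 2):
        key = f"{sequence[i + 1]}{flat[i:i + 3]}"
        counts[key] += 1
    n_windows = L - 2
    return {
        f"triplet_{key}": count / n_windows for key, count in counts.items()
    }


# ---------------------------------------------------------------------------
# Base composition
# ---------------------------------------------------------------------------


def composition_features(sequence: str) -> dict[str, float]:
    """Mono/dinucleotide counts and percentages plus G+C / A+U compositions."""
    L = len(sequence)
    if L < 2:
        raise ValueError(f"composition features need L >= 2, got L = {L}")
    out: dict[str, float] = {}
    for nt in NUCLEOTIDES:
        c = sequence.count(nt)
        out[f"count_{nt}"] = float(c)
        out[f"pct_{nt}"] = c / L * 100.0
    for a in NUCLEOTIDES:
        for b in NUCLEOTIDES:
            di = a + b
            c = sum(1 for i in range(L - 1) if sequence[i : i + 2] == di)
            out[f"count_{di}"] = float(c)
            out[f"pct_{di}"] = c / (L - 1) * 100.0
    gc = sequence.count("G") + sequence.count("C")
    au = sequence.count("A") + sequence.count("U")
    out["count_G+C"] = float(gc)
    out["count_A+U"] = float(au)
    out["pct_G+C"] = gc / L * 100.0
    out["pct_A+U"] = au / L * 100.0
    out["length"] = float(L)
    return out


def gc_percent(sequence: str) -> float:
    """%(G+C) of a sequence."""
    return (sequence.count("G") + sequence.count("C")) / len(sequence) * 100.0


# ---------------------------------------------------------------------------
# Structural / thermodynamic ratios
# ---------------------------------------------------------------------------


def thermo_features(structure: SecondaryStructure, sequence: str) -> dict[str, float]:
    """Structural counts and the MFE-derived normalized ratios.

    Requires ``annotate_motifs`` to have populated the structure. Zero
    denominators (no stems, no loops, no pairs, zero GC) yield 0.
    """
    L = len(sequence)
    if len(structure) != L:
        raise ValueError("sequence/structure length mismatch")
    dG = structure.mfe / L
    pct_gc = gc_percent(sequence)
    return {
        "tot_bp": float(structure.tot_bp),
        "n_stems": float(structure.n_stems),
        "n_loops": float(structure.n_loops),
        "loop_length": float(structure.loop_length),
        "dP": structure.tot_bp / L,
        "avg_bp": _safe_div(structure.tot_bp, structure.n_stems),
        "MFE": structure.mfe,
        "dG": dG,
        "MFE1": _safe_div(dG, pct_gc),
        "MFE2": _safe_div(dG, structure.n_stems),
        "MFE3": _safe_div(dG, structure.n_loops),
        "MFE4": _safe_div(dG, structure.tot_bp),
    }


# ---------------------------------------------------------------------------
# Ensemble (pair-probability) features
# ---------------------------------------------------------------------------


def entropy_features(structure: SecondaryStructure, L: int) -> dict[str, float]:
    """Q, dQ and dD from the base-pair probability matrix.

    Q = -sum_{i<j} p_ij log2 p_ij (terms with p_ij = 0 contribute 0);
    dQ = Q / L; dD = sum_{i<j} p_ij (1 - p_ij) / L.
    """
    if structure.pair_probs is None:
        raise ValueError(
            "pair probabilities missing: fold with a partition-function-capable "
            "backend (e.g. ViennaBackend) or attach a fixture matrix"
        )
    p = np.triu(np.asarray(structure.pair_probs, dtype=float), k=1)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("pair probabilities must lie in [0, 1]")
    nz = p[p > 0]
    q = float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0
    dd = float((p * (1.0 - p)).sum()) / L
    return {"Q": q, "dQ": q / L, "dD": dd}


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Random permutation of a sequence preserving dinucleotide composition.

    Altschul–Erikson shuffle: build the multigraph of nucleotide transitions,
    pick random last edges into each vertex that form a tree to the end
    vertex, then shuffle the remaining out-edge lists and walk the Euler
    path.
    """
    if len(sequence) < 3:
        return sequence
    edges: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        edges.setdefault(a, []).append(b)
    start, end = sequence[0], sequence[-1]
    vertices = sorted(edges.keys() | set(sequence))

    for _ in range(200):  # rejection-sample a valid last-edge tree
        last: dict[str, str] = {}
        for v in vertices:
            if v != end and edges.get(v):
                last[v] = edges[v][rng.integers(len(edges[v]))]
        # check: from every vertex with out-edges, following last-edges reaches end
        ok = True
        for v in last:
            seen = set()
            cur = v
            while cur != end and cur in last and cur not in seen:
                seen.add(cur)
                cur = last[cur]
            if cur != end:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - pathological composition
        return sequence

    shuffled_edges: dict[str, list[str]] = {}
    for v, outs in edges.items():
        rest = list(outs)
        if v in last:
            rest.remove(last[v])
        rng.shuffle(rest)
        shuffled_edges[v] = rest + ([last[v]] if v in last else [])

    walk = [start]
    cur = start
    while shuffled_edges.get(cur):
        nxt = shuffled_edges[cur].pop(0)
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


def shuffle_z_score(
    sequence: str,
    observed_dd: float,
    backend: FoldingBackend,
    n_shuffles: int,
    rng: np.random.Generator,
) -> float:
    """z-score of dD against dinucleotide-shuffled, refolded variants.

    Returns 0 when ``n_shuffles`` < 2 or when the shuffle distribution is
    degenerate (zero standard deviation).
    """
    if n_shuffles < 2:
        return 0.0
    L = len(sequence)
    dds = np.empty(n_shuffles)
    for m in range(n_shuffles):
        shuf = dinucleotide_shuffle(sequence, rng)
        st = fold_with_probabilities(backend, shuf)
        dds[m] = entropy_features(st, L)["dD"]
    sd = dds.std(ddof=1)
    if sd == 0:
        return 0.0
    return float((observed_dd - dds.mean()) / sd)


# ---------------------------------------------------------------------------
# The full descriptor
# ---------------------------------------------------------------------------


def featurize(
    record: RnaRecord,
    structure: SecondaryStructure,
    *,
    backend: FoldingBackend | None = None,
    zd_shuffles: int = 100,
    seed: int | None = None,
    manifest: FeatureManifest | None = None,
) -> FeatureVector:
    """Compute the ordered 93-feature descriptor for one hairpin.

    ``structure`` must be motif-annotated and aligned to the record. The
    ensemble features Q/dQ/dD require ``structure.pair_probs``; zD
    additionally needs a ``backend`` to refold ``zd_shuffles``
    dinucleotide-preserving shuffles (seeded; pass ``zd_shuffles=0`` to skip,
    in which case zD = 0).
    """
    manifest = manifest or default_manifest()
    if len(structure) != len(record):
        raise ValueError(
            f"record {record.id!r}: structure length {len(structure)} != "
            f"sequence length {len(record)}"
        )
    if structure.pair_probs is None and backend is not None:
        structure.pair_probs = backend.pairing_probabilities(record.sequence)
    feats: dict[str, float] = {}
    feats.update(triplet_elements(record.sequence, structure.dotbracket))
    feats.update(composition_features(record.sequence))
    feats.update(thermo_features(structure, record.sequence))
    feats.update(entropy_features(structure, len(record)))
    if zd_shuffles > 0:
        if backend is None:
            raise ValueError("zD needs a folding backend (or set zd_shuffles=0)")
        rng = np.random.default_rng(seed)
        feats["zD"] = shuffle_z_score(
            record.sequence, feats["dD"], backend, zd_shuffles, rng
        )
    else:
        feats["zD"] = 0.0
    values = np.array([feats[name] for name in manifest.names])
    return FeatureVector(
        record_id=record.id, values=values, manifest_version=manifest.version
    )


def featurize_many(
    pairs,
    *,
    backend: FoldingBackend | None = None,
    zd_shuffles: int = 0,
    seed: int | None = None,
    manifest: FeatureManifest | None = None,
):
    """Featurize an iterable of (record, structure) pairs into a DataFrame.

    Returns a pandas DataFrame: ``id`` column, then the 93 manifest-ordered
    feature columns. ``zd_shuffles`` defaults to 0 here (bulk pipelines skip
    the shuffle ensemble unless explicitly requested).
    """
    import pandas as pd

    manifest = manifest or default_manifest()
    rows = []
    for rec, st in pairs:
        fv = featurize(
            rec,
            st,
            backend=backend,
            zd_shuffles=zd_shuffles,
            seed=seed,
            manifest=manifest,
        )
        rows.append([rec.id, *fv.values.tolist()])
    return pd.DataFrame(rows, columns=["id", *manifest.names])


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------


def fit_scaler(matrix: np.ndarray):
    """Fit a per-feature standard scaler (zero mean, unit variance).

    Constant features scale to 0. Requires at least two rows.
    """
    from sklearn.preprocessing import StandardScaler

    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("fit_scaler needs a 2-D matrix with >= 2 rows")
    return StandardScaler().fit(matrix)


def apply_scaler(scaler, matrix: np.ndarray) -> np.ndarray:
    return scaler.transform(np.asarray(matrix, dtype=float))
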