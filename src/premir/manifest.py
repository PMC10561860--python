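"""The canonical 93-feature manifest.

The descriptor computed for every hairpin is a fixed, ordered list of 93
features in four groups:

* ``triplet`` (32) — Triplet-SVM style sequence/structure elements: for every
  window of three adjacent positions, ')' is first rewritten to '(', giving 8
  possible 3-character pairing patterns; keyed by the middle nucleotide this
  yields 4 x 8 = 32 bins, reported as frequencies (count / (L - 2)).
* ``composition`` (45) — mononucleotide counts and percentages (8),
  overlapping-dinucleotide counts and percentages (32), G+C and A+U counts and
  percentages (4), and sequence length L (1).
* ``structural`` (6) — base-pair count ``tot_bp``, stem count ``n_stems``
  (stacked runs of more than three pairs), hairpin-loop count ``n_loops``,
  total hairpin-loop length, base-pairing propensity ``dP = tot_bp / L`` and
  ``avg_bp = tot_bp / n_stems``.
* ``thermodynamic`` (10) — MFE, ``dG = MFE / L``, the normalized ratios
  MFE1-MFE4, Shannon entropy ``Q`` of the base-pairing ensemble, its
  length-normalized form ``dQ``, the ensemble base-pair distance per
  nucleotide ``dD`` and its shuffle z-score ``zD``.

The manifest is versioned; feature vectors and trained models carry the
version and refuse to mix versions.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MANIFEST_VERSION",
    "NUCLEOTIDES",
    "TRIPLET_PATTERNS",
    "FeatureManifest",
    "default_manifest",
]

MANIFEST_VERSION = "1.0"

NUCLEOTIDES = ("A", "C", "G", "U")

#: The 8 three-position pairing patterns after mapping ')' to '(' — the
#: Triplet-SVM ordering.
TRIPLET_PATTERNS = ("(((", "((.", "(..", "(.(", ".((", ".(.", "..(", "...")


@dataclass(frozen=True)
class FeatureEntry:
    name: str
    group: str  # triplet | composition | structural | thermodynamic
    formula: str


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered, versioned list of the 93 feature definitions."""

    version: str
    entries: tuple[FeatureEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("manifest feature names must be unique")
        if len(names) != 93:
            raise ValueError(f"manifest must have exactly 93 entries, got {len(names)}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def group_names(self, group: str) -> list[str]:
        return [e.name for e in self.entries if e.group == group]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __len__(self) -> int:
        return len(self.entries)


def _build_entries() -> tuple[FeatureEntry, ...]:
    entries: list[FeatureEntry] = []
    # 32 triplet bins: middle nucleotide major, pattern minor
    for nt in NUCLEOTIDES:
        for pat in TRIPLET_PATTERNS:
            entries.append(
                FeatureEntry(
                    name=f"triplet_{nt}{pat}",
                    group="triplet",
                    formula=f"count(middle={nt}, pattern={pat!r}) / (L - 2)",
                )
            )
    # composition: mono counts + percentages
    for nt in NUCLEOTIDES:
        entries.append(FeatureEntry(f"count_{nt}", "composition", f"|{nt}|"))
    for nt in NUCLEOTIDES:
        entries.append(FeatureEntry(f"pct_{nt}", "composition", f"|{nt}| / L * 100"))
    # dinucleotide counts + percentages (overlapping windows)
    dints = [a + b for a in NUCLEOTIDES for b in NUCLEOTIDES]
    for d in dints:
        entries.append(FeatureEntry(f"count_{d}", "composition", f"|{d}|"))
    for d in dints:
        entries.append(FeatureEntry(f"pct_{d}", "composition", f"|{d}| / (L - 1) * 100"))
    entries += [
        FeatureEntry("count_G+C", "composition", "|G| + |C|"),
        FeatureEntry("count_A+U", "composition", "|A| + |U|"),
        FeatureEntry("pct_G+C", "composition", "(|G| + |C|) / L * 100"),
        FeatureEntry("pct_A+U", "composition", "(|A| + |U|) / L * 100"),
        FeatureEntry("length", "composition", "L"),
        # structural
        FeatureEntry("tot_bp", "structural", "number of base pairs"),
        FeatureEntry("n_stems", "structural", "stacked-pair runs of length >= 4"),
        FeatureEntry("n_loops", "structural", "number of hairpin loops"),
        FeatureEntry("loop_length", "structural", "total unpaired bases in hairpin loops"),
        FeatureEntry("dP", "structural", "tot_bp / L"),
        FeatureEntry("avg_bp", "structural", "tot_bp / n_stems"),
        # thermodynamic
        FeatureEntry("MFE", "thermodynamic", "minimum free energy (kcal/mol)"),
        FeatureEntry("dG", "thermodynamic", "MFE / L"),
        FeatureEntry("MFE1", "thermodynamic", "dG / pct_GC"),
        FeatureEntry("MFE2", "thermodynamic", "dG / n_stems"),
        FeatureEntry("MFE3", "thermodynamic", "dG / n_loops"),
        FeatureEntry("MFE4", "thermodynamic", "dG / tot_bp"),
        FeatureEntry("Q", "thermodynamic", "-sum_{i<j} p_ij log2 p_ij"),
        FeatureEntry("dQ", "thermodynamic", "Q / L"),
        FeatureEntry("dD", "thermodynamic", "sum_{i<j} p_ij (1 - p_ij) / L"),
        FeatureEntry("zD", "thermodynamic", "(dD - mean_shuffled) / sd_shuffled"),
    ]
    return tuple(entries)


_DEFAULT = FeatureManifest(version=MANIFEST_VERSION, entries=_build_entries())


def default_manifest() -> FeatureManifest:
    """The package's canonical manifest (version 1.0, 93 features)."""
    return _DEFAULT


def to_json(manifest: FeatureManifest | None = None) -> str:
    """Serialize a manifest to the shipped JSON schema."""
    import json

    manifest = manifest or _DEFAULT
    return json.dumps(
        {
            "version": manifest.version,
            "features": [
                {"name": e.name, "group": e.group, "formula": e.formula}
                for e in manifest.entries
            ],
        },
        indent=1,
    )


def load_json(path) -> FeatureManifest:
    """Load a manifest from its JSON serialization."""
    import json

    with open(path) as fh:
        raw = json.load(fh)
    return FeatureManifest(
        version=raw["version"],
        entries=tuple(
            FeatureEntry(f["name"], f["group"], f["formula"]) for f in raw["features"]
        ),
    )


def shipped_manifest_path():
    """Path of the versioned manifest data file bundled with the package."""
    from importlib.resources import files

    return files("premir").joinpath("data/manifest_v1.json")
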