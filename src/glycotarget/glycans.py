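"""Permethylated benzyl O-glycoside mass arithmetic and glycome annotation.

The cellular O-glycome reporter/amplification (CORA) assay feeds cells
benzyl-GalNAc; the secreted benzyl O-glycosides are permethylated and read
out by LC-ESI-MS. This module computes the monoisotopic mass and [M+H]+ m/z
of such species from a monosaccharide composition, assigns compositions to
observed peaks by exhaustive enumeration, and normalizes peak intensities
into relative glycome abundances.

Mass model
----------
A glycan of R residues, fully permethylated after benzylation of the
anomeric position, has neutral monoisotopic mass

    M = sum(residue masses) + water + benzyl + CH2 * n_sites

with ``n_sites = sum(base methylation sites per residue) - (R - 1)``:
every glycosidic bond consumes one hydroxyl that would otherwise be
methylated. NeuAc contributes 6 sites (4 OH, N-methyl, and the carboxyl
methyl ester formed during permethylation). Branching never changes the
count, so masses are topology-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MONOSACCHARIDES",
    "MASS",
    "GlycanComposition",
    "GlycomeEntry",
    "GlycomeProfile",
    "permethylated_benzyl_mass",
    "mz",
    "assign_composition",
    "normalize_glycome",
    "read_peak_table",
    "write_glycome_table",
]


@dataclass(frozen=True)
class MonosaccharideClass:
    """One monosaccharide class: residue mass and free-methylation sites."""

    name: str
    residue_mass: float  # monoisotopic Da (dehydrated residue)
    base_methyl_sites: int


#: The four classes CORA O-glycomics distinguishes by mass.
MONOSACCHARIDES: dict[str, MonosaccharideClass] = {
    "Hex": MonosaccharideClass("Hex", 162.052824, 4),
    "HexNAc": MonosaccharideClass("HexNAc", 203.079373, 4),
    "dHex": MonosaccharideClass("dHex", 146.057909, 3),
    "NeuAc": MonosaccharideClass("NeuAc", 291.095417, 6),
}

#: Canonical class order for labels and tie-breaking.
_CLASS_ORDER = ("Hex", "HexNAc", "dHex", "NeuAc")


class MassConstants:
    """Fixed monoisotopic constants (Da)."""

    WATER = 18.010565
    METHYLENE = 14.015650  # CH2 added per methylation site
    BENZYL = 90.046950  # C7H6: benzyl replacing the anomeric OH hydrogen
    PROTON = 1.007276


MASS = MassConstants


@dataclass(frozen=True)
class GlycanComposition:
    """Immutable monosaccharide-class counts for one O-glycan.

    Parameters
    ----------
    counts
        Mapping class name -> non-negative count; at least one residue.
    label
        Optional free-text name, e.g. ``"T antigen"``.
    """

    counts: Mapping[str, int]
    label: str | None = None

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for name, n in self.counts.items():
            if name not in MONOSACCHARIDES:
                raise ValueError(
                    f"unknown monosaccharide class {name!r}; "
                    f"known: {sorted(MONOSACCHARIDES)}"
                )
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {name} must be a non-negative integer")
            if n:
                clean[name] = n
        if sum(clean.values()) < 1:
            raise ValueError("composition must contain at least one residue")
        object.__setattr__(self, "counts", dict(clean))

    @property
    def n_residues(self) -> int:
        return sum(self.counts.values())

    def key(self) -> tuple[int, ...]:
        """Counts in canonical class order (Hex, HexNAc, dHex, NeuAc)."""
        return tuple(self.counts.get(c, 0) for c in _CLASS_ORDER)

    def __str__(self) -> str:
        return " ".join(
            f"{c}{self.counts[c]}" for c in _CLASS_ORDER if self.counts.get(c)
        )

    def __hash__(self) -> int:
        return hash(self.key())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanComposition):
            return NotImplemented
        return self.key() == other.key()


def permethylated_benzyl_mass(comp: GlycanComposition, *, benzyl: bool = True) -> float:
    """Neutral monoisotopic mass of the fully permethylated glycoside.

    With ``benzyl=False`` the free reducing end is assumed instead, i.e. the
    anomeric position carries a methyl like any other site (one extra CH2
    replaces the benzyl group). CORA readouts always use the benzyl form.
    """
    residues = sum(
        MONOSACCHARIDES[c].residue_mass * n for c, n in comp.counts.items()
    )
    n_sites = (
        sum(MONOSACCHARIDES[c].base_methyl_sites * n for c, n in comp.counts.items())
        - (comp.n_residues - 1)
    )
    mass = residues + MASS.WATER + n_sites * MASS.METHYLENE
    if benzyl:
        mass += MASS.BENZYL
    else:
        mass += MASS.METHYLENE  # anomeric OH methylated instead of benzylated
    return mass


def mz(comp: GlycanComposition, charge: int = 1, *, benzyl: bool = True) -> float:
    """[M + z H]z+ m/z of the permethylated (benzyl) glycoside.

    Peaks in CORA spectra are treated as singly protonated by default; this
    convention reproduces the canonical T (572.31), core 3 (613.33) and
    core 2 (1021.53) ions.
    """
    if not isinstance(charge, int) or charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge!r}")
    neutral = permethylated_benzyl_mass(comp, benzyl=benzyl)
    return (neutral + charge * MASS.PROTON) / charge


def assign_composition(
    observed_mz: float,
    bounds: Mapping[str, int] | int = 6,
    tolerance: float = 0.05,
    *,
    charge: int = 1,
) -> list[tuple[GlycanComposition, float]]:
    """Enumerate compositions whose theoretical m/z matches an observed peak.

    Parameters
    ----------
    observed_mz
        Observed peak position (Da).
    bounds
        Maximum residue count per class, either one integer for all classes
        or a per-class mapping.
    tolerance
        Absolute matching window in Da (must be positive).

    Returns
    -------
    list of (composition, error) pairs with ``error = theoretical - observed``,
    sorted by \\|error\\|, ties broken by fewer residues then canonical class
    order. Empty when nothing matches.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if isinstance(bounds, int):
        bounds = {c: bounds for c in _CLASS_ORDER}
    ranges = [range(int(bounds.get(c, 0)) + 1) for c in _CLASS_ORDER]
    hits: list[tuple[GlycanComposition, float]] = []
    for counts in product(*ranges):
        if sum(counts) == 0:
            continue
        comp = GlycanComposition(dict(zip(_CLASS_ORDER, counts)))
        err = mz(comp, charge) - observed_mz
        if abs(err) <= tolerance:
            hits.append((comp, err))
    hits.sort(key=lambda h: (abs(h[1]), h[0].n_residues, h[0].key()))
    return hits


@dataclass(frozen=True)
class GlycomeEntry:
    composition: GlycanComposition | None
    observed_mz: float
    intensity: float
    relative_abundance: float = 0.0


@dataclass
class GlycomeProfile:
    """An annotated, abundance-normalized O-glycome."""

    entries: list[GlycomeEntry] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            comp = e.composition
            rows.append(
                {
                    "label": comp.label if comp and comp.label else "",
                    "composition": str(comp) if comp else "",
                    "theoretical_mz": mz(comp) if comp else float("nan"),
                    "observed_mz": e.observed_mz,
                    "error_da": (mz(comp) - e.observed_mz) if comp else float("nan"),
                    "intensity": e.intensity,
                    "relative_abundance": e.relative_abundance,
                }
            )
        return pd.DataFrame(rows)


def normalize_glycome(
    entries: Iterable[tuple[GlycanComposition | None, float, float]],
) -> GlycomeProfile:
    """Convert (composition, observed m/z, intensity) triples into a profile.

    Relative abundance of each entry is its intensity over the summed
    intensity of all entries ("contribution to the glycome"); input order is
    preserved. All-zero or negative intensities are rejected.
    """
    entries = list(entries)
    if any(i < 0 for _, _, i in entries):
        raise ValueError("intensities must be non-negative")
    total = sum(i for _, _, i in entries)
    if total <= 0:
        raise ValueError("at least one entry must have positive intensity")
    return GlycomeProfile(
        [
            GlycomeEntry(comp, omz, inten, inten / total)
            for comp, omz, inten in entries
        ]
    )


def read_peak_table(path) -> pd.DataFrame:
    """Read a TSV peak table with columns ``mz`` and ``intensity``."""
    df = pd.read_csv(path, sep="\t")
    missing = {"mz", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    return df


def annotate_peaks(
    peaks: pd.DataFrame,
    bounds: Mapping[str, int] | int = 6,
    tolerance: float = 0.05,
) -> GlycomeProfile:
    """Assign a composition to every peak and normalize abundances.

    Peaks with no composition within tolerance are kept unannotated so the
    abundance denominator still covers the whole profile.
    """
    entries: list[tuple[GlycanComposition | None, float, float]] = []
    for _, row in peaks.iterrows():
        hits = assign_composition(float(row["mz"]), bounds, tolerance)
        comp = hits[0][0] if hits else None
        entries.append((comp, float(row["mz"]), float(row["intensity"])))
    return normalize_glycome(entries)


def write_glycome_table(profile: GlycomeProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
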