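"""STn glycopeptide search and glycosite localization from MS/MS data.

A transparent re-implementation of the second, glycopeptide-focused search
stage: tryptic digestion of a protein database, candidate generation with a
fixed carbamidomethyl-Cys modification and variable Met oxidation and STn
(NeuAc-GalNAc, +494.1748 Da on Ser/Thr), oxonium-ion prefiltering of HCD
spectra, precursor matching in ppm, scoring by counted b/y fragment
matches, and glycosite localization via site-determining ions.

Fragment model: singly charged b/y ions. Because HCD frequently strips
O-glycans from the backbone, an STn-carrying fragment matches if EITHER its
intact (+494.1748) or its fully deglycosylated form lies within the
fragment tolerance.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pmass

logger = logging.getLogger(__name__)

__all__ = [
    "ModificationSpec",
    "STN",
    "CARBAMIDOMETHYL",
    "OXIDATION",
    "Spectrum",
    "PeptideCandidate",
    "GlycopeptideMatch",
    "OXONIUM_HEXNAC",
    "OXONIUM_NEUAC",
    "OXONIUM_NEUAC_H2O_LOSS",
    "digest",
    "peptide_mass",
    "fragment_ions",
    "oxonium_filter",
    "localize",
    "search",
]

PROTON = 1.007276
WATER = 18.010565

#: Monoisotopic residue masses (pyteomics standard table).
RESIDUE_MASS: dict[str, float] = dict(_pmass.std_aa_mass)

_VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

# Diagnostic oxonium ions (singly charged immonium-type glycan fragments):
# HexNAc oxonium C8H14NO5+ and NeuAc oxonium C11H18NO8+ (and its water loss).
OXONIUM_HEXNAC = 204.0867
OXONIUM_NEUAC = 292.1027
OXONIUM_NEUAC_H2O_LOSS = 274.0921


@dataclass(frozen=True)
class ModificationSpec:
    name: str
    delta_mass: float
    targets: frozenset[str]
    fixed: bool = False
    max_per_peptide: int = 2

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"{self.name}: modification targets must be non-empty")


STN = ModificationSpec("STn", 494.1748, frozenset("ST"), fixed=False, max_per_peptide=3)
CARBAMIDOMETHYL = ModificationSpec(
    "Carbamidomethyl", 57.02146, frozenset("C"), fixed=True
)
OXIDATION = ModificationSpec("Oxidation", 15.9949, frozenset("M"), fixed=False)

DEFAULT_MODS = (CARBAMIDOMETHYL, OXIDATION, STN)


@dataclass
class Spectrum:
    """One MS/MS spectrum: precursor and a sorted peak list."""

    id: str
    precursor_mz: float
    charge: int
    peaks: list[tuple[float, float]]  # (m/z, intensity), sorted by m/z

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks)
        if any(i < 0 for _, i in self.peaks):
            raise ValueError(f"spectrum {self.id}: negative intensity")

    def has_peak(self, mz_value: float, tol: float) -> bool:
        import bisect

        mzs = [p[0] for p in self.peaks]
        i = bisect.bisect_left(mzs, mz_value - tol)
        return i < len(mzs) and mzs[i] <= mz_value + tol


@dataclass(frozen=True)
class PeptideCandidate:
    """A tryptic peptide with 1-based inclusive protein coordinates."""

    accession: str
    sequence: str
    start: int
    end: int
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinates inconsistent with sequence length")
        if not 0 <= self.missed_cleavages <= 2:
            raise ValueError("missed_cleavages must be within 0..2")


@dataclass
class GlycopeptideMatch:
    spectrum_id: str
    peptide: PeptideCandidate
    placements: tuple[tuple[int, ModificationSpec], ...]  # (1-based pos, spec)
    precursor_error_ppm: float
    n_matched_ions: int
    glycosites: tuple[int, ...]  # protein coordinates of localized STn sites
    site_localized: bool

    @property
    def n_stn(self) -> int:
        return sum(1 for _, m in self.placements if m.name == STN.name)


def digest(
    sequence: str,
    max_missed: int = 2,
    accession: str = "protein",
    min_length: int = 1,
) -> list[PeptideCandidate]:
    """Tryptic digestion: cleave C-terminal to K/R except when followed by P.

    Returns every peptide with 0..max_missed internal cleavage sites,
    with 1-based inclusive protein coordinates.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty protein sequence")
    for i, aa in enumerate(sequence):
        if aa not in _VALID_AA:
            raise ValueError(f"invalid residue {aa!r} at position {i + 1}")
    # cut points: index i means a cut between sequence[i-1] and sequence[i]
    cuts = [0]
    for i in range(1, len(sequence)):
        if sequence[i - 1] in "KR" and sequence[i] != "P":
            cuts.append(i)
    cuts.append(len(sequence))
    peptides = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(cuts))):
            seq = sequence[cuts[a] : cuts[b]]
            if len(seq) < min_length:
                continue
            peptides.append(
                PeptideCandidate(
                    accession=accession,
                    sequence=seq,
                    start=cuts[a] + 1,
                    end=cuts[b],
                    missed_cleavages=b - a - 1,
                )
            )
    return peptides


def _check_placements(
    sequence: str, placements: Iterable[tuple[int, ModificationSpec]]
) -> None:
    for pos, spec in placements:
        if not 1 <= pos <= len(sequence):
            raise ValueError(f"placement position {pos} outside peptide")
        if sequence[pos - 1] not in spec.targets:
            raise ValueError(
                f"{spec.name} cannot be placed on {sequence[pos - 1]}{pos}"
            )


def peptide_mass(
    pep: PeptideCandidate | str,
    placements: Sequence[tuple[int, ModificationSpec]] = (),
) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification deltas."""
    seq = pep.sequence if isinstance(pep, PeptideCandidate) else pep
    _check_placements(seq, placements)
    return (
        sum(RESIDUE_MASS[a] for a in seq)
        + WATER
        + sum(spec.delta_mass for _, spec in placements)
    )


def fragment_ions(
    sequence: str,
    placements: Sequence[tuple[int, ModificationSpec]] = (),
    *,
    glycan_loss: bool = True,
) -> list[tuple[str, float]]:
    """Singly charged b/y ion m/z values for a modified peptide.

    Glycan-carrying fragments are emitted in both intact and fully
    deglycosylated (backbone) form when ``glycan_loss`` is set.
    """
    _check_placements(sequence, placements)
    n = len(sequence)
    delta_at = [0.0] * (n + 1)  # 1-based
    glycan_at = [0.0] * (n + 1)
    for pos, spec in placements:
        delta_at[pos] += spec.delta_mass
        if spec.name == STN.name:
            glycan_at[pos] += spec.delta_mass
    prefix_mass = [0.0] * (n + 1)
    prefix_glycan = [0.0] * (n + 1)
    for i in range(1, n + 1):
        prefix_mass[i] = prefix_mass[i - 1] + RESIDUE_MASS[sequence[i - 1]] + delta_at[i]
        prefix_glycan[i] = prefix_glycan[i - 1] + glycan_at[i]
    total = prefix_mass[n]
    total_glycan = prefix_glycan[n]
    ions: list[tuple[str, float]] = []
    for i in range(1, n):  # b1..b(n-1), y1..y(n-1)
        b = prefix_mass[i] + PROTON
        y = (total - prefix_mass[i]) + WATER + PROTON
        ions.append((f"b{i}", b))
        ions.append((f"y{n - i}", y))
        if glycan_loss and prefix_glycan[i] > 0:
            ions.append((f"b{i}-glycan", b - prefix_glycan[i]))
        if glycan_loss and (total_glycan - prefix_glycan[i]) > 0:
            ions.append((f"y{n - i}-glycan", y - (total_glycan - prefix_glycan[i])))
    return ions


def oxonium_filter(spectrum: Spectrum, fragment_tol: float = 0.01) -> bool:
    """True iff the spectrum shows both diagnostic STn oxonium ions: a
    HexNAc oxonium (204.0867) AND a NeuAc oxonium (292.1027 or its water
    loss 274.0921), each within the fragment tolerance."""
    if not spectrum.peaks:
        logger.info("spectrum %s is empty; oxonium filter false", spectrum.id)
        return False
    has_hexnac = spectrum.has_peak(OXONIUM_HEXNAC, fragment_tol)
    has_neuac = spectrum.has_peak(OXONIUM_NEUAC, fragment_tol) or spectrum.has_peak(
        OXONIUM_NEUAC_H2O_LOSS, fragment_tol
    )
    return has_hexnac and has_neuac


def _count_matched(
    spectrum: Spectrum, ions: Iterable[tuple[str, float]], tol: float
) -> int:
    return sum(1 for _, m in ions if spectrum.has_peak(m, tol))


def _variable_placements(
    sequence: str,
    mods: Sequence[ModificationSpec],
    allow_stn: bool,
) -> Iterable[tuple[tuple[int, ModificationSpec], ...]]:
    """All legal variable-modification placement sets (fixed mods excluded)."""
    per_mod_options: list[list[tuple[tuple[int, ModificationSpec], ...]]] = []
    for spec in mods:
        if spec.fixed:
            continue
        if spec.name == STN.name and not allow_stn:
            per_mod_options.append([()])
            continue
        sites = [i + 1 for i, a in enumerate(sequence) if a in spec.targets]
        opts: list[tuple[tuple[int, ModificationSpec], ...]] = [()]
        for k in range(1, min(spec.max_per_peptide, len(sites)) + 1):
            for combo in itertools.combinations(sites, k):
                opts.append(tuple((p, spec) for p in combo))
        per_mod_options.append(opts)
    for parts in itertools.product(*per_mod_options):
        yield tuple(itertools.chain.from_iterable(parts))


def _fixed_placements(
    sequence: str, mods: Sequence[ModificationSpec]
) -> tuple[tuple[int, ModificationSpec], ...]:
    out = []
    for spec in mods:
        if spec.fixed:
            out.extend((i + 1, spec) for i, a in enumerate(sequence) if a in spec.targets)
    return tuple(out)


def localize(
    pep: PeptideCandidate,
    spectrum: Spectrum,
    candidate_sites: Sequence[int],
    n_stn: int = 1,
    *,
    base_placements: Sequence[tuple[int, ModificationSpec]] = (),
    fragment_tol: float = 0.01,
) -> tuple[tuple[int, ...], bool]:
    """Pick the STn site placement best supported by site-determining ions.

    For every way of placing ``n_stn`` STn groups on the candidate Ser/Thr
    sites, count the matched fragments among ions whose m/z depends on the
    placement (site-determining ions). A unique argmax localizes the sites;
    ties return all tied placements' site union with ``localized=False``.

    Positions are 1-based within the peptide; the returned sites too.
    """
    if not candidate_sites:
        raise ValueError("at least one candidate site is required")
    if n_stn > len(candidate_sites):
        raise ValueError("more STn groups than candidate sites")
    combos = list(itertools.combinations(sorted(candidate_sites), n_stn))
    if len(combos) == 1:
        return combos[0], True
    ion_sets = {}
    for combo in combos:
        placements = tuple(base_placements) + tuple((p, STN) for p in combo)
        ion_sets[combo] = fragment_ions(pep.sequence, placements)
    # site-determining ions: those not shared (by m/z) across all placements
    common = None
    for ions in ion_sets.values():
        mzs = {round(m, 4) for _, m in ions}
        common = mzs if common is None else common & mzs
    scores = {}
    for combo, ions in ion_sets.items():
        determining = [(n, m) for n, m in ions if round(m, 4) not in common]
        scores[combo] = _count_matched(spectrum, determining, fragment_tol)
    best = max(scores.values())
    winners = [c for c, s in scores.items() if s == best]
    if len(winners) == 1 and best > 0:
        return winners[0], True
    sites = tuple(sorted({p for c in winners for p in c}))
    return sites, False


def _spectrum_charges(s: Spectrum) -> list[int]:
    if s.charge and s.charge >= 1:
        return [s.charge]
    warnings.warn(f"spectrum {s.id} has no charge; trying z=2 and z=3")
    return [2, 3]


def search(
    spectra: Iterable[Spectrum],
    proteins: Mapping[str, str],
    mods: Sequence[ModificationSpec] = DEFAULT_MODS,
    precursor_tol_ppm: float = 10.0,
    fragment_tol: float = 0.01,
    max_missed: int = 2,
    min_peptide_length: int = 5,
    max_peptide_length: int = 45,
) -> list[GlycopeptideMatch]:
    """Match each spectrum to its best-scoring (peptide, placements) pair.

    STn-containing interpretations are only considered for spectra that
    pass the oxonium prefilter. Candidates must match the precursor within
    ``precursor_tol_ppm``; they are scored by the number of matched b/y
    ions, ties broken by fewer modifications then lexicographic peptide.
    """
    proteins = dict(proteins)
    if not proteins:
        raise ValueError("no protein sequences provided")
    peptides: list[PeptideCandidate] = []
    for acc, seq in proteins.items():
        for pep in digest(seq, max_missed, accession=acc, min_length=min_peptide_length):
            if len(pep.sequence) <= max_peptide_length:
                peptides.append(pep)

    # precompute candidate neutral masses for every placement set
    candidates: list[tuple[float, PeptideCandidate, tuple]] = []
    for pep in peptides:
        fixed = _fixed_placements(pep.sequence, mods)
        for var in _variable_placements(pep.sequence, mods, allow_stn=True):
            placements = fixed + var
            m = peptide_mass(pep, placements)
            candidates.append((m, pep, placements))
    candidates.sort(key=lambda c: c[0])
    masses = [c[0] for c in candidates]

    import bisect

    matches: list[GlycopeptideMatch] = []
    for s in spectra:
        if s.charge == 0:
            warnings.warn(f"spectrum {s.id}: charge 0, skipped")
            continue
        stn_ok = oxonium_filter(s, fragment_tol)
        best: tuple | None = None
        for z in _spectrum_charges(s):
            neutral = (s.precursor_mz - PROTON) * z
            tol_da = neutral * precursor_tol_ppm * 1e-6
            lo = bisect.bisect_left(masses, neutral - tol_da)
            hi = bisect.bisect_right(masses, neutral + tol_da)
            for m, pep, placements in candidates[lo:hi]:
                n_stn = sum(1 for _, sp in placements if sp.name == STN.name)
                if n_stn > 0 and not stn_ok:
                    continue
                theo_mz = (m + z * PROTON) / z
                ppm = (theo_mz - s.precursor_mz) / s.precursor_mz * 1e6
                ions = fragment_ions(pep.sequence, placements)
                score = _count_matched(s, ions, fragment_tol)
                key = (-score, len(placements), pep.sequence)
                if best is None or key < best[0]:
                    best = (key, pep, placements, ppm, score, z)
        if best is None or best[4] == 0:
            continue
        _, pep, placements, ppm, score, z = best
        stn_positions = sorted(p for p, sp in placements if sp.name == STN.name)
        if stn_positions:
            cand_sites = [i + 1 for i, a in enumerate(pep.sequence) if a in "ST"]
            base = tuple(
                (p, sp) for p, sp in placements if sp.name != STN.name
            )
            sites, localized = localize(
                pep,
                s,
                cand_sites,
                n_stn=len(stn_positions),
                base_placements=base,
                fragment_tol=fragment_tol,
            )
        else:
            sites, localized = (), False
        glycosites = tuple(pep.start + p - 1 for p in sites)
        matches.append(
            GlycopeptideMatch(
                spectrum_id=s.id,
                peptide=pep,
                placements=placements,
                precursor_error_ppm=ppm,
                n_matched_ions=score,
                glycosites=glycosites,
                site_localized=localized,
            )
        )
    return matches


def read_fasta(path) -> dict[str, str]:
    """Load a protein FASTA into an accession -> sequence mapping."""
    from Bio import SeqIO

    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_mgf(path) -> list[Spectrum]:
    """Load an MGF peak list into Spectrum objects."""
    from pyteomics import mgf

    out = []
    with mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = params.get("charge")
            z = int(charge[0]) if charge else 0
            out.append(
                Spectrum(
                    id=str(params.get("title", f"scan_{len(out)}")),
                    precursor_mz=float(params["pepmass"][0]),
                    charge=z,
                    peaks=list(
                        zip(entry["m/z array"].tolist(), entry["intensity array"].tolist())
                    ),
                )
            )
    return out


def matches_to_frame(matches: Sequence[GlycopeptideMatch]):
    """Flatten matches into a report table (one row per spectrum match)."""
    import pandas as pd

    rows = []
    for m in matches:
        rows.append(
            {
                "spectrum_id": m.spectrum_id,
                "accession": m.peptide.accession,
                "peptide": m.peptide.sequence,
                "start": m.peptide.start,
                "end": m.peptide.end,
                "mods": ";".join(
                    f"{sp.name}@{pos}" for pos, sp in sorted(m.placements)
                ),
                "ppm_error": m.precursor_error_ppm,
                "n_matched_ions": m.n_matched_ions,
                "glycosites": ";".join(str(g) for g in m.glycosites),
                "localized": m.site_localized,
            }
        )
    return pd.DataFrame(rows)


def glycosite_summary(matches: Sequence[GlycopeptideMatch]):
    """Per-protein summary of localized STn glycosites."""
    import pandas as pd

    per_protein: dict[str, set[int]] = {}
    for m in matches:
        if m.site_localized and m.glycosites:
            per_protein.setdefault(m.peptide.accession, set()).update(m.glycosites)
    rows = [
        {
            "accession": acc,
            "n_glycosites": len(sites),
            "glycosites": ";".join(str(s) for s in sorted(sites)),
        }
        for acc, sites in sorted(per_protein.items())
    ]
    return pd.DataFrame(rows)
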