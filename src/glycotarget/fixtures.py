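"""Seeded synthetic-data generators for every pipeline input.

Each generator is a pure function of its configuration (seed included):
identical configurations yield byte-identical files. The generators emulate
the shapes of the real inputs — search-engine identification exports,
tissue-atlas annotation tables, HCD glycopeptide spectra and survival
cohorts — not their full biological richness (no chromatography, isotope
envelopes or intensity models).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import sitemap
from .sitemap import (
    CARBAMIDOMETHYL,
    PROTON,
    STN,
    PeptideCandidate,
    Spectrum,
    digest,
    fragment_ions,
    peptide_mass,
)
from .targetscore import DEFAULT_TISSUE_SYSTEMS

__all__ = [
    "FixtureConfig",
    "toy_fasta_path",
    "make_identifications",
    "make_annotations",
    "make_glyco_spectra",
    "make_cohort",
]

_LEVEL_NAMES = ("nd", "low", "medium", "high")


@dataclass(frozen=True)
class FixtureConfig:
    """Configuration shared by all generators."""

    seed: int = 0
    # identifications
    n_proteins: int = 500
    planted_overlap: int = 100
    membrane_fraction: float = 0.4
    # annotations
    n_annotation_proteins: int = 100
    n_tissues: int = 12
    planted_target: bool = True
    # spectra
    n_spectra: int = 50
    peak_dropout: float = 0.0
    decoy_peaks: int = 0
    # cohort
    group_sizes: tuple[int, int] = (100, 100)
    hazard_ratio: float = 1.0
    baseline_hazard: float = 0.05  # events per month in the reference group
    censoring_rate: float = 0.2  # expected censored fraction in the reference group

    def __post_init__(self) -> None:
        for name in ("membrane_fraction", "peak_dropout", "censoring_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0 + (name == "membrane_fraction"):
                raise ValueError(f"{name} must be a valid fraction, got {v}")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if self.n_proteins < 2:
            raise ValueError("n_proteins must be >= 2")
        if self.n_tissues < 3:
            raise ValueError("n_tissues must be >= 3")


def toy_fasta_path() -> Path:
    """Path to the bundled toy FASTA (3 invented Ser/Thr-rich membrane-like
    proteins)."""
    return Path(str(resources.files("glycotarget") / "data" / "toy_proteins.fasta"))


def _accessions(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(1, n + 1)]


def make_identifications(cfg: FixtureConfig, out_dir: Path) -> tuple[Path, Path]:
    """Write a two-method identification TSV and a membrane registry file.

    A pool of ``n_proteins`` accessions is split so that exactly
    ``planted_overlap`` of them appear in both the RPS and SCX lists; PEP
    scores are Beta(1, 20) draws and membrane membership is assigned to a
    ``membrane_fraction`` subset of the pool.
    """
    if cfg.planted_overlap > cfg.n_proteins // 2:
        raise ValueError("planted_overlap cannot exceed half the protein pool")
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pool = _accessions(cfg.n_proteins)
    shared = pool[: cfg.planted_overlap]
    remaining = pool[cfg.planted_overlap :]
    half = len(remaining) // 2
    only_a, only_b = remaining[:half], remaining[half : 2 * half]
    rows = []
    for method, accs in (("RPS", shared + only_a), ("SCX", shared + only_b)):
        peps = rng.beta(1, 20, size=len(accs))
        psms = rng.integers(1, 50, size=len(accs))
        for acc, pep, n in zip(accs, peps, psms):
            rows.append(
                {
                    "accession": acc,
                    "gene": f"GENE{acc[1:]}",
                    "pep": round(float(pep), 8),
                    "method": method,
                    "n_psms": int(n),
                }
            )
    ids_path = out_dir / "identifications.tsv"
    pd.DataFrame(rows).to_csv(ids_path, sep="\t", index=False)

    n_membrane = int(round(cfg.membrane_fraction * cfg.n_proteins))
    membrane = sorted(rng.choice(pool, size=n_membrane, replace=False).tolist())
    reg_path = out_dir / "membrane_registry.txt"
    reg_path.write_text("".join(f"{a}\n" for a in membrane))
    return ids_path, reg_path


def make_annotations(cfg: FixtureConfig, out_dir: Path) -> Path:
    """Write a tissue-atlas-style annotation TSV.

    Decoy proteins are broadly expressed (healthy levels drawn from
    low/medium/high) with random membrane, tumor and prognosis flags. When
    ``planted_target`` is set, the first protein gets the ideal-target
    profile: membrane-located, tumor-high, unfavorable prognosis, and a
    single low-level healthy tissue.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # one tissue from each penalized system, the rest from the full vocabulary
    systems_pool = sorted(DEFAULT_TISSUE_SYSTEMS)
    per_system = {"reproductive": "testis", "immune": "spleen", "nervous": "cerebral cortex"}
    other_pool = ["liver", "kidney", "lung", "heart muscle", "skin", "colon",
                  "stomach", "pancreas", "esophagus", "skeletal muscle"]
    tissues = list(per_system.values())
    extra = [t for t in other_pool + systems_pool if t not in tissues]
    tissues += extra[: cfg.n_tissues - len(tissues)]
    accs = [f"T{i:05d}" for i in range(1, cfg.n_annotation_proteins + 1)]
    rows = []
    for i, acc in enumerate(accs):
        if cfg.planted_target and i == 0:
            row = {
                "accession": acc,
                "plasma_membrane": 1,
                "tumor_level": "high",
                "prognosis_unfavorable": 1,
            }
            for j, t in enumerate(tissues):
                row[t] = "low" if j == len(tissues) - 1 else "nd"
        else:
            row = {
                "accession": acc,
                "plasma_membrane": int(rng.random() < 0.5),
                "tumor_level": _LEVEL_NAMES[rng.integers(0, 4)],
                "prognosis_unfavorable": int(rng.random() < 0.3),
            }
            for t in tissues:
                row[t] = _LEVEL_NAMES[rng.integers(1, 4)]
        rows.append(row)
    path = out_dir / "annotations.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def _theoretical_spectrum(
    pep: PeptideCandidate, placements, precursor_charge: int = 2
) -> tuple[float, list[tuple[float, float]]]:
    """Precursor m/z and the complete noiseless peak list (b/y ions in intact
    and glycan-stripped form, plus the STn diagnostic oxonium ions)."""
    neutral = peptide_mass(pep, placements)
    precursor = (neutral + precursor_charge * PROTON) / precursor_charge
    peaks = [(m, 100.0) for _, m in fragment_ions(pep.sequence, placements)]
    peaks += [
        (sitemap.OXONIUM_HEXNAC, 500.0),
        (sitemap.OXONIUM_NEUAC, 400.0),
        (sitemap.OXONIUM_NEUAC_H2O_LOSS, 300.0),
    ]
    return precursor, sorted(set(peaks))


def make_glyco_spectra(
    cfg: FixtureConfig, fasta: Path | None, out_dir: Path
) -> tuple[Path, Path]:
    """Write an MGF of synthetic STn glycopeptide HCD spectra plus a
    ground-truth TSV.

    Tryptic peptides (with up to 2 missed cleavages) containing at least
    one Ser/Thr are sampled from the FASTA; one STn placement is drawn per
    spectrum; the spectrum holds every singly charged b/y ion in both
    intact and glycan-stripped form plus the diagnostic oxonium ions.
    ``peak_dropout`` removes backbone peaks at random; ``decoy_peaks`` adds
    uniform noise peaks.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = Path(fasta) if fasta else toy_fasta_path()
    proteins = sitemap.read_fasta(fasta)
    candidates: list[PeptideCandidate] = []
    for acc, seq in proteins.items():
        for pep in digest(seq, max_missed=2, accession=acc, min_length=6):
            if len(pep.sequence) <= 30 and any(a in "ST" for a in pep.sequence):
                candidates.append(pep)
    if not candidates:
        raise ValueError("FASTA yields no S/T-containing tryptic peptides")
    truth_rows = []
    mgf_blocks = []
    for i in range(cfg.n_spectra):
        pep = candidates[int(rng.integers(0, len(candidates)))]
        st_sites = [k + 1 for k, a in enumerate(pep.sequence) if a in "ST"]
        site = int(st_sites[int(rng.integers(0, len(st_sites)))])
        fixed = tuple(
            (k + 1, CARBAMIDOMETHYL)
            for k, a in enumerate(pep.sequence)
            if a == "C"
        )
        placements = fixed + ((site, STN),)
        precursor, peaks = _theoretical_spectrum(pep, placements)
        if cfg.peak_dropout > 0:
            kept = []
            for mz_v, inten in peaks:
                is_oxonium = inten >= 300.0
                if is_oxonium or rng.random() >= cfg.peak_dropout:
                    kept.append((mz_v, inten))
            peaks = kept
        for _ in range(cfg.decoy_peaks):
            peaks.append((float(rng.uniform(150.0, 2000.0)), float(rng.uniform(1, 50))))
        peaks = sorted(peaks)
        sid = f"synthetic_scan_{i:04d}"
        lines = [
            "BEGIN IONS",
            f"TITLE={sid}",
            f"PEPMASS={precursor:.6f}",
            "CHARGE=2+",
        ]
        lines += [f"{mz_v:.6f} {inten:.1f}" for mz_v, inten in peaks]
        lines.append("END IONS")
        mgf_blocks.append("\n".join(lines))
        truth_rows.append(
            {
                "spectrum_id": sid,
                "accession": pep.accession,
                "peptide": pep.sequence,
                "start": pep.start,
                "end": pep.end,
                "stn_site_peptide": site,
                "stn_site_protein": pep.start + site - 1,
            }
        )
    mgf_path = out_dir / "spectra.mgf"
    mgf_path.write_text("\n\n".join(mgf_blocks) + "\n")
    truth_path = out_dir / "spectra_truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    return mgf_path, truth_path


def simulate_cohort_frame(cfg: FixtureConfig) -> pd.DataFrame:
    """Simulate a two-group survival cohort as a DataFrame.

    Event times are exponential with the configured baseline hazard
    (group B's hazard is baseline x hazard_ratio); censoring times are
    independent exponentials tuned so the expected censored fraction in the
    reference group equals ``censoring_rate``.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    n_a, n_b = cfg.group_sizes
    if min(n_a, n_b) < 1:
        raise ValueError("both groups must be non-empty")
    h = cfg.baseline_hazard
    rows = []
    if cfg.censoring_rate > 0:
        h_c = h * cfg.censoring_rate / (1 - cfg.censoring_rate)
    else:
        h_c = 0.0
    for group, n, hazard in (("A", n_a, h), ("B", n_b, h * cfg.hazard_ratio)):
        t_event = rng.exponential(1 / hazard, size=n)
        if h_c > 0:
            t_cens = rng.exponential(1 / h_c, size=n)
        else:
            t_cens = np.full(n, np.inf)
        time = np.minimum(t_event, t_cens)
        event = t_event <= t_cens
        for j in range(n):
            rows.append(
                {
                    "id": f"{group}{j:04d}",
                    "group": group,
                    "time": round(float(time[j]), 6),
                    "event": int(event[j]),
                }
            )
    return pd.DataFrame(rows)


def make_cohort(cfg: FixtureConfig, out_dir: Path) -> Path:
    """Write a two-group survival cohort TSV (see simulate_cohort_frame)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "cohort.tsv"
    simulate_cohort_frame(cfg).to_csv(path, sep="\t", index=False)
    return path
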