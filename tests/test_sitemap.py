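"""Tryptic digestion, glycopeptide search and glycosite localization."""

import itertools

import pandas as pd
import pytest

from glycotarget import sitemap
from glycotarget.fixtures import FixtureConfig, make_glyco_spectra
from glycotarget.sitemap import (
    PROTON,
    STN,
    PeptideCandidate,
    Spectrum,
    digest,
    fragment_ions,
    localize,
    oxonium_filter,
    peptide_mass,
    read_fasta,
    read_mgf,
    search,
)

# monoisotopic atomic masses for the elemental oracle
_ATOM = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052, "O": 15.9949146221, "S": 31.97207069}
_AA_FORMULA = {  # dehydrated residues
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO", "V": "C5H9NO",
    "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO", "I": "C6H11NO", "N": "C4H6N2O2",
    "D": "C4H5NO3", "Q": "C5H8N2O2", "K": "C6H12N2O", "E": "C5H7NO3", "M": "C5H9NOS",
    "H": "C6H7N3O", "F": "C9H9NO", "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
}


def oracle_peptide_mass(seq: str) -> float:
    import re

    atoms: dict[str, float] = {}
    for aa in seq:
        for el, num in re.findall(r"([A-Z])(\d*)", _AA_FORMULA[aa]):
            atoms[el] = atoms.get(el, 0) + (int(num) if num else 1)
    atoms["H"] = atoms.get("H", 0) + 2
    atoms["O"] = atoms.get("O", 0) + 1
    return sum(_ATOM[el] * n for el, n in atoms.items())


def brute_force_digest(seq: str, max_missed: int) -> set[str]:
    """Enumerate all substrings delimited by legal tryptic cut points."""
    cuts = [0] + [
        i for i in range(1, len(seq)) if seq[i - 1] in "KR" and seq[i] != "P"
    ] + [len(seq)]
    out = set()
    for a, b in itertools.combinations(range(len(cuts)), 2):
        if b - a - 1 <= max_missed:
            out.add(seq[cuts[a] : cuts[b]])
    return out


class TestDigest:
    def test_proline_suppresses_cleavage(self):
        peps = {p.sequence for p in digest("AKRPCK")}
        assert {"AK", "AKRPCK", "RPCK"} <= peps
        assert "R" not in peps  # KR|P boundary is not cut

    def test_no_cut_sites_yields_full_sequence(self):
        peps = digest("ACDEFG")
        assert len(peps) == 1 and peps[0].sequence == "ACDEFG"
        assert (peps[0].start, peps[0].end) == (1, 6)

    @pytest.mark.parametrize("seq,max_missed", [("AKRPCK", 2), ("KKK", 2), ("MSTKRATKPR", 1)])
    def test_matches_bruteforce_enumeration(self, seq, max_missed):
        got = {p.sequence for p in digest(seq, max_missed)}
        assert got == brute_force_digest(seq, max_missed)

    def test_kkk_positions(self):
        peps = digest("KKK", max_missed=2)
        assert sorted((p.sequence, p.start) for p in peps) == [
            ("K", 1), ("K", 2), ("K", 3), ("KK", 1), ("KK", 2), ("KKK", 1),
        ]

    def test_invalid_residue_reported_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            digest("AKXK")

    def test_prefix_closure_under_missed_cleavages(self, toy_fasta):
        """Every missed-cleavage peptide is a concatenation of adjacent
        fully cleaved peptides."""
        seq = next(iter(read_fasta(toy_fasta).values()))
        full = [p for p in digest(seq, 0)]
        joined = {"".join(p.sequence for p in full[i : i + k + 1])
                  for k in range(3) for i in range(len(full) - k)}
        for p in digest(seq, 2):
            assert p.sequence in joined


class TestPeptideMass:
    def test_single_glycine(self):
        assert peptide_mass("G") == pytest.approx(75.03203, abs=1e-4)

    @pytest.mark.parametrize("seq", ["PEPTIDE", "SAMPLER", "TESTING"])
    def test_matches_elemental_oracle(self, seq):
        assert peptide_mass(seq) == pytest.approx(oracle_peptide_mass(seq), abs=1e-4)

    def test_stn_adds_exactly_its_delta(self):
        base = peptide_mass("ASTK")
        assert peptide_mass("ASTK", [(2, STN)]) - base == pytest.approx(494.1748)

    def test_placement_on_wrong_residue_rejected(self):
        with pytest.raises(ValueError, match="cannot be placed"):
            peptide_mass("AGGK", [(2, STN)])


def spectrum_from(peaks, sid="s", precursor=500.0, charge=2):
    return Spectrum(sid, precursor, charge, [(m, 100.0) for m in peaks])


class TestOxoniumFilter:
    def test_requires_both_diagnostic_ions(self):
        both = spectrum_from([204.087, 292.103])
        hexnac_only = spectrum_from([204.087])
        neuac_only = spectrum_from([292.103])
        assert oxonium_filter(both)
        assert not oxonium_filter(hexnac_only)
        assert not oxonium_filter(neuac_only)

    def test_water_loss_neuac_accepted(self):
        assert oxonium_filter(spectrum_from([204.0867, 274.0921]))

    def test_tolerance_boundary(self):
        assert not oxonium_filter(spectrum_from([204.137, 292.153]), fragment_tol=0.01)

    def test_empty_spectrum_false_not_error(self):
        assert oxonium_filter(Spectrum("e", 500.0, 2, [])) is False


def _noiseless_spectrum(pep, placements, charge=2):
    neutral = peptide_mass(pep, placements)
    peaks = [(m, 100.0) for _, m in fragment_ions(pep.sequence, placements)]
    peaks += [(sitemap.OXONIUM_HEXNAC, 500.0), (sitemap.OXONIUM_NEUAC, 400.0)]
    return Spectrum("t", (neutral + charge * PROTON) / charge, charge, peaks)


class TestLocalize:
    def pep(self, seq):
        return PeptideCandidate("X", seq, 1, len(seq), 0)

    def test_single_candidate_site_is_forced(self):
        pep = self.pep("AGSGK")
        s = _noiseless_spectrum(pep, ((3, STN),))
        assert localize(pep, s, [3]) == ((3,), True)

    def test_planted_site_determining_ions_pick_correct_site(self):
        pep = self.pep("ASGGTGK")
        s = _noiseless_spectrum(pep, ((5, STN),))
        sites, ok = localize(pep, s, [2, 5])
        assert ok and sites == (5,)

    def test_no_site_determining_ions_means_ambiguous(self):
        pep = self.pep("ASGGTGK")
        s = spectrum_from([204.0867, 292.1027], precursor=800.0)
        sites, ok = localize(pep, s, [2, 5])
        assert not ok
        assert set(sites) == {2, 5}


@pytest.fixture(scope="module")
def noiseless_run(toy_fasta, tmp_path_factory):
    out = tmp_path_factory.mktemp("mgf")
    cfg = FixtureConfig(seed=13, n_spectra=15)
    mgf_path, truth_path = make_glyco_spectra(cfg, toy_fasta, out)
    spectra = read_mgf(mgf_path)
    proteins = read_fasta(toy_fasta)
    matches = search(spectra, proteins)
    truth = pd.read_csv(truth_path, sep="\t")
    return spectra, matches, truth


class TestSearch:
    def test_noiseless_recovery_is_complete(self, noiseless_run):
        """Every synthetic spectrum yields its generating peptide with the
        correct localized glycosite."""
        _, matches, truth = noiseless_run
        by_id = {m.spectrum_id: m for m in matches}
        assert len(by_id) == len(truth)
        for _, row in truth.iterrows():
            m = by_id[row.spectrum_id]
            assert m.peptide.sequence == row.peptide
            assert m.site_localized
            assert list(m.glycosites) == [row.stn_site_protein]

    def test_reported_tolerances_respected(self, noiseless_run):
        _, matches, _ = noiseless_run
        assert matches
        for m in matches:
            assert abs(m.precursor_error_ppm) <= 10.0

    def test_no_stn_report_without_oxonium_ions(self, noiseless_run, toy_fasta):
        spectra, _, _ = noiseless_run
        proteins = read_fasta(toy_fasta)
        oxonium = {sitemap.OXONIUM_HEXNAC, sitemap.OXONIUM_NEUAC,
                   sitemap.OXONIUM_NEUAC_H2O_LOSS}
        stripped = [
            Spectrum(s.id, s.precursor_mz, s.charge,
                     [p for p in s.peaks if round(p[0], 4) not in oxonium])
            for s in spectra
        ]
        for m in search(stripped, proteins):
            assert m.n_stn == 0

    def test_precursor_shift_kills_match(self, noiseless_run, toy_fasta):
        spectra, _, _ = noiseless_run
        proteins = read_fasta(toy_fasta)
        shifted = [
            Spectrum(s.id, s.precursor_mz * (1 + 50e-6), s.charge, list(s.peaks))
            for s in spectra
        ]
        assert search(shifted, proteins) == []

    def test_dropout_never_invents_sites(self, toy_fasta, tmp_path):
        """With 30% backbone-peak dropout, reported glycosites are still
        always drawn from the peptide's own Ser/Thr positions."""
        cfg = FixtureConfig(seed=21, n_spectra=15, peak_dropout=0.3, decoy_peaks=5)
        mgf_path, _ = make_glyco_spectra(cfg, toy_fasta, tmp_path)
        proteins = read_fasta(toy_fasta)
        for m in search(read_mgf(mgf_path), proteins):
            st_positions = {
                m.peptide.start + i
                for i, a in enumerate(m.peptide.sequence)
                if a in "ST"
            }
            assert set(m.glycosites) <= st_positions

    def test_empty_fasta_rejected(self):
        with pytest.raises(ValueError):
            search([], {})
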