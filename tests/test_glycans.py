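"""Mass arithmetic for permethylated benzyl O-glycosides.

The independent oracle used throughout is elemental-formula summation:
each glycoside's molecular formula is assembled atom by atom from its
residues, the benzyl aglycone, the water terminus and the methyl groups,
and its monoisotopic mass computed from atomic masses. This never goes
through the residue-mass bookkeeping the implementation uses.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycotarget.glycans import (
    MONOSACCHARIDES,
    GlycanComposition,
    annotate_peaks,
    assign_composition,
    mz,
    normalize_glycome,
    permethylated_benzyl_mass,
)

# monoisotopic atomic masses for the elemental oracle
_ATOM = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052, "O": 15.9949146221}

# elemental formulas of the dehydrated residues
_RESIDUE_FORMULA = {
    "Hex": {"C": 6, "H": 10, "O": 5},
    "HexNAc": {"C": 8, "H": 13, "N": 1, "O": 5},
    "dHex": {"C": 6, "H": 10, "O": 4},
    "NeuAc": {"C": 11, "H": 17, "N": 1, "O": 8},
}
_BASE_SITES = {"Hex": 4, "HexNAc": 4, "dHex": 3, "NeuAc": 6}


def oracle_benzyl_mass(counts: dict[str, int]) -> float:
    """Elemental-formula mass of the permethylated benzyl glycoside."""
    atoms = {"C": 0, "H": 0, "N": 0, "O": 0}
    for cls, n in counts.items():
        for el, k in _RESIDUE_FORMULA[cls].items():
            atoms[el] += k * n
    atoms["H"] += 2
    atoms["O"] += 1  # terminal water
    atoms["C"] += 7
    atoms["H"] += 6  # benzyl replaces the anomeric H
    r = sum(counts.values())
    n_sites = sum(_BASE_SITES[c] * n for c, n in counts.items()) - (r - 1)
    atoms["C"] += n_sites
    atoms["H"] += 2 * n_sites  # each methylation adds CH2
    return sum(_ATOM[el] * k for el, k in atoms.items())


PRINTED_MZ = [
    # (composition, printed value, decimals)
    ({"Hex": 1, "HexNAc": 1}, 572.31, 2),  # T antigen
    ({"Hex": 1, "HexNAc": 1, "NeuAc": 1}, 933.48, 2),  # sialyl-T
    ({"HexNAc": 1, "NeuAc": 1}, 729.4, 1),  # STn
    ({"HexNAc": 2}, 613.33, 2),  # core 3
    ({"Hex": 1, "HexNAc": 2}, 817.43, 2),  # core 2 trisaccharide
    ({"Hex": 2, "HexNAc": 2}, 1021.53, 2),  # core 2 tetrasaccharide
    ({"Hex": 2, "HexNAc": 2, "dHex": 1}, 1195.62, 2),
    ({"Hex": 2, "HexNAc": 2, "NeuAc": 1}, 1382.71, 2),
    ({"Hex": 3, "HexNAc": 3}, 1470.76, 2),
    ({"Hex": 1, "HexNAc": 1, "NeuAc": 2}, 1294.7, 1),  # di-sialyl-T
]


@pytest.mark.parametrize("counts,printed,dp", PRINTED_MZ)
def test_canonical_o_glycan_ions(counts, printed, dp):
    """[M+H]+ of each canonical O-glycome ion matches its known value at the
    precision it is conventionally reported."""
    assert round(mz(GlycanComposition(counts)), dp) == printed


@pytest.mark.parametrize("counts,printed,dp", PRINTED_MZ)
def test_mass_matches_elemental_oracle(counts, printed, dp):
    assert permethylated_benzyl_mass(GlycanComposition(counts)) == pytest.approx(
        oracle_benzyl_mass(counts), abs=1e-4
    )


def test_single_hex_base_case():
    m = permethylated_benzyl_mass(GlycanComposition({"Hex": 1}))
    assert m == pytest.approx(162.052824 + 18.010565 + 90.046950 + 4 * 14.015650, abs=1e-6)


def test_doubly_charged_mz():
    comp = GlycanComposition({"Hex": 2, "HexNAc": 2})
    expected = (oracle_benzyl_mass(comp.counts) + 2 * 1.007276) / 2
    assert mz(comp, charge=2) == pytest.approx(expected, abs=1e-3)
    assert round(mz(comp, charge=2), 2) == 511.27


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError, match="unknown monosaccharide"):
        GlycanComposition({"Pent": 1})
    with pytest.raises(ValueError, match="at least one residue"):
        GlycanComposition({"Hex": 0})
    with pytest.raises(ValueError, match="charge"):
        mz(GlycanComposition({"Hex": 1}), charge=0)


@st.composite
def compositions(draw):
    counts = {
        c: draw(st.integers(min_value=0, max_value=4)) for c in MONOSACCHARIDES
    }
    if sum(counts.values()) == 0:
        counts["Hex"] = 1
    return counts


@settings(max_examples=60, deadline=None)
@given(compositions(), st.sampled_from(sorted(MONOSACCHARIDES)))
def test_residue_additivity(counts, cls):
    """Adding one residue of class c raises the neutral mass by exactly
    residue_mass(c) + (base_sites(c) - 1) * CH2, independent of topology."""
    base = permethylated_benzyl_mass(GlycanComposition(counts))
    more = dict(counts)
    more[cls] = more.get(cls, 0) + 1
    grown = permethylated_benzyl_mass(GlycanComposition(more))
    m = MONOSACCHARIDES[cls]
    assert grown - base == pytest.approx(
        m.residue_mass + (m.base_methyl_sites - 1) * 14.015650, abs=1e-9
    )


@settings(max_examples=40, deadline=None)
@given(compositions())
def test_assignment_inverts_mz(counts):
    """Assigning a composition's own computed m/z returns it at rank 1."""
    comp = GlycanComposition(counts)
    hits = assign_composition(mz(comp), bounds=5, tolerance=0.05)
    assert hits and hits[0][0] == comp


@pytest.mark.parametrize(
    "observed,expected_top",
    [
        (933.48, {"Hex": 1, "HexNAc": 1, "NeuAc": 1}),
        (1470.76, {"Hex": 3, "HexNAc": 3}),
    ],
)
def test_known_peak_assignments(observed, expected_top):
    hits = assign_composition(observed, bounds=6, tolerance=0.05)
    assert hits[0][0] == GlycanComposition(expected_top)


def test_assignment_below_smallest_mass_is_empty():
    assert assign_composition(100.0, bounds=6, tolerance=0.01) == []


def test_normalize_glycome_basic_and_scale_invariance():
    comp = GlycanComposition({"Hex": 1})
    entries = [(comp, 326.17, 1.0), (comp, 326.17, 2.0), (comp, 326.17, 7.0)]
    prof = normalize_glycome(entries)
    assert [e.relative_abundance for e in prof.entries] == pytest.approx([0.1, 0.2, 0.7])
    scaled = normalize_glycome([(c, m, 13 * i) for c, m, i in entries])
    assert [e.relative_abundance for e in scaled.entries] == pytest.approx([0.1, 0.2, 0.7])


def test_normalize_glycome_random_profile_sums_to_one():
    rng = np.random.default_rng(0)
    comp = GlycanComposition({"Hex": 1})
    entries = [(comp, 326.17, float(x)) for x in rng.uniform(0.1, 10, size=50)]
    prof = normalize_glycome(entries)
    assert sum(e.relative_abundance for e in prof.entries) == pytest.approx(1.0, abs=1e-9)


def test_normalize_rejects_degenerate_intensities():
    comp = GlycanComposition({"Hex": 1})
    with pytest.raises(ValueError):
        normalize_glycome([(comp, 326.17, 0.0)])
    with pytest.raises(ValueError):
        normalize_glycome([(comp, 326.17, -1.0)])


def test_annotate_peaks_roundtrip(tmp_path):
    import pandas as pd

    comps = [GlycanComposition(c) for c, _, _ in PRINTED_MZ[:4]]
    peaks = pd.DataFrame({"mz": [mz(c) for c in comps], "intensity": [4.0, 3.0, 2.0, 1.0]})
    prof = annotate_peaks(peaks)
    assert [e.composition for e in prof.entries] == comps
    assert sum(e.relative_abundance for e in prof.entries) == pytest.approx(1.0)
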