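"""Compute O-glycome m/z values and annotate a small peak list.

Builds the canonical short O-glycans, prints their permethylated-benzyl
[M+H]+ m/z, then assigns compositions to a simulated peak table and
normalizes relative abundances.
"""

import pandas as pd

from glycotarget.glycans import GlycanComposition, annotate_peaks, mz

glycans = {
    "T antigen": {"Hex": 1, "HexNAc": 1},
    "sialyl-T": {"Hex": 1, "HexNAc": 1, "NeuAc": 1},
    "STn": {"HexNAc": 1, "NeuAc": 1},
    "core 3": {"HexNAc": 2},
    "core 2 tetrasaccharide": {"Hex": 2, "HexNAc": 2},
}

print("Permethylated benzyl glycoside [M+H]+ m/z:")
for name, counts in glycans.items():
    comp = GlycanComposition(counts, label=name)
    print(f"  {name:24s} {comp}:  {mz(comp):.2f}")

# a toy glycome: three peaks at the theoretical positions, with intensities
peaks = pd.DataFrame(
    {
        "mz": [mz(GlycanComposition(c)) for c in list(glycans.values())[:3]],
        "intensity": [60.0, 30.0, 10.0],
    }
)
profile = annotate_peaks(peaks, bounds=6, tolerance=0.05)
print("\nAnnotated glycome (relative abundance = intensity / total):")
print(profile.to_frame()[["composition", "observed_mz", "relative_abundance"]])
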