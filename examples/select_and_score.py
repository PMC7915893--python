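"""Select membrane proteins from two fractionation methods and rank them
by Target Score.

Generates a synthetic two-method identification export and a tissue-atlas
style annotation table (with one planted ideal target), runs the
filter -> PEP top-N -> intersect funnel, then ranks by Target Score. The
planted profile (membrane-located, tumor-high, poor prognosis, sparse
healthy expression) should come out on top.
"""

from pathlib import Path

from glycotarget.fixtures import FixtureConfig, make_annotations, make_identifications
from glycotarget.selection import read_identifications, read_registry, select_common
from glycotarget.targetscore import rank_proteins, read_annotations

out = Path("scratch/example_select")
cfg = FixtureConfig(seed=1, n_proteins=500, planted_overlap=120, membrane_fraction=0.5)

ids_path, reg_path = make_identifications(cfg, out)
common = select_common(
    read_identifications(ids_path), read_registry(reg_path), top_n=100
)
print(f"proteins common to RPS and SCX top-100: {len(common)}")
print(common.head())

ann_path = make_annotations(cfg, out)
ranked = rank_proteins(read_annotations(ann_path))
print("\nTop 5 by Target Score (higher = more targetable):")
print(ranked.head()[["accession", "score", "rank"]].to_string(index=False))
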