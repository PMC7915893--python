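"""Target Score: ranking candidate surface glycoproteins by targetability.

The score rewards plasma-membrane localization, tumor abundance and
association with unfavorable prognosis, and penalizes expression in healthy
tissues — with an extra multiplier for reproductive, immune and nervous
tissues, where off-target binding is least acceptable. Expression levels
use the four-step immunohistochemistry vocabulary of tissue atlases
(not detected / low / medium / high, coded 0-3).

score = w_membrane * [membrane]
      + w_tumor_per_level * tumor_level
      + w_prognosis * [unfavorable prognosis]
      - aggregate_over_healthy_tissues( w_healthy_per_level
                                        * system_multiplier(tissue)
                                        * level )

All weights are configurable (`ScoreWeights`), so an alternative published
weighting can be dropped in without code changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionLevel",
    "TissueExpression",
    "ProteinAnnotation",
    "ScoreWeights",
    "DEFAULT_TISSUE_SYSTEMS",
    "target_score",
    "score_breakdown",
    "rank_proteins",
    "read_annotations",
]


class ExpressionLevel(IntEnum):
    """Ordinal IHC staining level."""

    not_detected = 0
    low = 1
    medium = 2
    high = 3

    @classmethod
    def parse(cls, text: str) -> "ExpressionLevel":
        key = str(text).strip().lower().replace(" ", "_")
        aliases = {"nd": "not_detected", "none": "not_detected", "": "not_detected"}
        key = aliases.get(key, key)
        try:
            return cls[key]
        except KeyError:
            raise ValueError(f"unknown expression level {text!r}") from None


#: Body systems that carry an extra penalty when expressing the candidate.
PENALIZED_SYSTEMS = frozenset({"reproductive", "immune", "nervous"})

#: Bundled tissue -> system map (HPA-style tissue vocabulary, abridged).
DEFAULT_TISSUE_SYSTEMS: dict[str, str] = {
    "testis": "reproductive",
    "ovary": "reproductive",
    "prostate": "reproductive",
    "endometrium": "reproductive",
    "placenta": "reproductive",
    "fallopian tube": "reproductive",
    "seminal vesicle": "reproductive",
    "epididymis": "reproductive",
    "cervix": "reproductive",
    "breast": "reproductive",
    "spleen": "immune",
    "lymph node": "immune",
    "tonsil": "immune",
    "thymus": "immune",
    "bone marrow": "immune",
    "appendix": "immune",
    "cerebral cortex": "nervous",
    "cerebellum": "nervous",
    "hippocampus": "nervous",
    "caudate": "nervous",
    "hypothalamus": "nervous",
    "spinal cord": "nervous",
    "peripheral nerve": "nervous",
}


@dataclass(frozen=True)
class TissueExpression:
    tissue: str
    level: ExpressionLevel
    system: str = "other"  # reproductive | immune | nervous | other
    cell_type: str | None = None

    def __post_init__(self) -> None:
        if not self.tissue:
            raise ValueError("tissue must be non-empty")


@dataclass(frozen=True)
class ProteinAnnotation:
    """Per-protein evidence consumed by the score."""

    accession: str
    plasma_membrane: bool
    tumor_level: ExpressionLevel
    healthy_profile: tuple[TissueExpression, ...] = ()
    unfavorable_prognosis: bool = False

    def __post_init__(self) -> None:
        tissues = [t.tissue for t in self.healthy_profile]
        if len(tissues) != len(set(tissues)):
            raise ValueError(f"{self.accession}: duplicate tissues in healthy profile")


@dataclass(frozen=True)
class ScoreWeights:
    w_membrane: float = 3.0
    w_tumor_per_level: float = 1.0
    w_prognosis: float = 2.0
    w_healthy_per_level: float = 1.0
    system_penalty_multiplier: float = 2.0
    healthy_aggregation: str = "mean"  # mean | sum

    def __post_init__(self) -> None:
        for name in (
            "w_membrane",
            "w_tumor_per_level",
            "w_prognosis",
            "w_healthy_per_level",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.system_penalty_multiplier < 1:
            raise ValueError("system_penalty_multiplier must be >= 1")
        if self.healthy_aggregation not in ("mean", "sum"):
            raise ValueError("healthy_aggregation must be 'mean' or 'sum'")

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "ScoreWeights":
        return cls(**{k: cfg[k] for k in cfg})


def _healthy_penalty(ann: ProteinAnnotation, w: ScoreWeights) -> float:
    terms = [
        w.w_healthy_per_level
        * (w.system_penalty_multiplier if t.system in PENALIZED_SYSTEMS else 1.0)
        * int(t.level)
        for t in ann.healthy_profile
    ]
    if not terms:
        return 0.0
    total = sum(terms)
    return total / len(terms) if w.healthy_aggregation == "mean" else total


def score_breakdown(
    ann: ProteinAnnotation, w: ScoreWeights = ScoreWeights()
) -> dict[str, float]:
    """The score and its additive components."""
    membrane = w.w_membrane * float(ann.plasma_membrane)
    tumor = w.w_tumor_per_level * int(ann.tumor_level)
    prognosis = w.w_prognosis * float(ann.unfavorable_prognosis)
    penalty = _healthy_penalty(ann, w)
    return {
        "membrane": membrane,
        "tumor": tumor,
        "prognosis": prognosis,
        "healthy_penalty": penalty,
        "score": membrane + tumor + prognosis - penalty,
    }


def target_score(ann: ProteinAnnotation, w: ScoreWeights = ScoreWeights()) -> float:
    return score_breakdown(ann, w)["score"]


def rank_proteins(
    annotations: Sequence[ProteinAnnotation], w: ScoreWeights = ScoreWeights()
) -> pd.DataFrame:
    """Score every annotation and return a ranked table.

    Descending score; ties broken by accession; ranks are dense (equal
    scores share a rank).
    """
    if not annotations:
        raise ValueError("at least one annotation is required")
    rows = []
    for ann in annotations:
        bd = score_breakdown(ann, w)
        rows.append({"accession": ann.accession, **bd})
    df = pd.DataFrame(rows).sort_values(
        ["score", "accession"], ascending=[False, True], kind="mergesort"
    )
    df["rank"] = df["score"].rank(method="dense", ascending=False).astype(int)
    return df.reset_index(drop=True)[
        ["accession", "score", "rank", "membrane", "tumor", "prognosis", "healthy_penalty"]
    ]


def read_annotations(
    path,
    tissue_systems: Mapping[str, str] | None = None,
) -> list[ProteinAnnotation]:
    """Read an annotation TSV.

    Expected columns: ``accession``, ``plasma_membrane`` (0/1),
    ``tumor_level``, ``prognosis_unfavorable`` (0/1), then one column per
    healthy tissue holding a level in {nd, low, medium, high}. Tissues not
    in the system map are treated as "other"; missing level cells are
    treated as not detected (logged).
    """
    systems = {k.lower(): v for k, v in (tissue_systems or DEFAULT_TISSUE_SYSTEMS).items()}
    df = pd.read_csv(path, sep="\t")
    fixed = {"accession", "plasma_membrane", "tumor_level", "prognosis_unfavorable"}
    missing = fixed - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    tissue_cols = [c for c in df.columns if c not in fixed]
    out = []
    for _, row in df.iterrows():
        profile = []
        for col in tissue_cols:
            raw = row[col]
            if pd.isna(raw):
                logger.info("%s: missing level for %s, treating as not detected",
                            row["accession"], col)
                level = ExpressionLevel.not_detected
            else:
                level = ExpressionLevel.parse(raw)
            profile.append(
                TissueExpression(
                    tissue=col,
                    level=level,
                    system=systems.get(col.lower(), "other"),
                )
            )
        out.append(
            ProteinAnnotation(
                accession=str(row["accession"]),
                plasma_membrane=bool(int(row["plasma_membrane"])),
                tumor_level=ExpressionLevel.parse(row["tumor_level"]),
                healthy_profile=tuple(profile),
                unfavorable_prognosis=bool(int(row["prognosis_unfavorable"])),
            )
        )
    return out
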