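"""Clinical rating scales and structured-score → text prompt generation.

A continuous scale score is binned against severity breakpoints (half-open
``[lo, hi)`` bins, final bin closed at the range maximum), mapped to an
ordered severity label, substituted into a sentence template, and expanded
into lexically augmented variants.  The four default scales cover the core
dimensions assessed in Parkinson's disease work-ups: motor function
(MDS-UPDRS part III), anxiety (STAI), daytime sleepiness (ESS) and cognition
(CDT, where by clinical convention a *lower* drawing score is more impaired —
handled by the ``invert`` flag).

Scale definitions ship as a YAML file (:data:`DEFAULT_SCALES_PATH`) and are
fully user-overridable; no threshold is hard-coded in the logic.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .augment import Augmenter, augment_sentence
from .exceptions import ScoreRangeError, ValidationError

__all__ = [
    "ScaleDefinition",
    "ClinicalRecord",
    "PromptSet",
    "SCALE_ORDER",
    "DEFAULT_LABELS",
    "load_scale_definitions",
    "load_clinical_table",
    "categorize_score",
    "render_sentence",
    "build_prompt_set",
    "sample_training_prompt",
]

SCALE_ORDER = ("MDS-UPDRS", "STAI", "ESS", "CDT")
DEFAULT_LABELS = ("Mild", "Moderate", "Significant", "Serious")
PLACEHOLDER = "{label}"

#: CSV column name -> scale identifier for the clinical table layout
CSV_COLUMNS = {"updrs": "MDS-UPDRS", "stai": "STAI", "ess": "ESS", "cdt": "CDT"}


@dataclass(frozen=True)
class ScaleDefinition:
    """One clinical scale: range, severity breakpoints, labels, template.

    ``labels`` are ordered from least to most severe.  With ``invert`` set,
    low raw scores map to the most severe label (clock-drawing convention).
    """

    scale_id: str
    score_range: tuple[float, float]
    breakpoints: tuple[float, ...]
    labels: tuple[str, ...] = DEFAULT_LABELS
    template: str = ""
    invert: bool = False

    def __post_init__(self):
        lo, hi = self.score_range
        if not lo < hi:
            raise ValidationError(f"{self.scale_id}: empty score range [{lo}, {hi}]")
        bp = tuple(float(b) for b in self.breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValidationError(f"{self.scale_id}: breakpoints must strictly increase")
        if bp and not (lo < bp[0] and bp[-1] < hi):
            raise ValidationError(
                f"{self.scale_id}: breakpoints must lie strictly inside ({lo}, {hi})"
            )
        if len(self.labels) != len(bp) + 1:
            raise ValidationError(
                f"{self.scale_id}: need {len(bp) + 1} labels for {len(bp)} "
                f"breakpoints, got {len(self.labels)}"
            )
        if self.template.count(PLACEHOLDER) != 1:
            raise ValidationError(
                f"{self.scale_id}: template must contain exactly one "
                f"'{PLACEHOLDER}' placeholder"
            )
        object.__setattr__(self, "score_range", (float(lo), float(hi)))
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "labels", tuple(self.labels))

    def to_dict(self) -> dict:
        return {
            "scale_id": self.scale_id,
            "score_range": list(self.score_range),
            "breakpoints": list(self.breakpoints),
            "labels": list(self.labels),
            "template": self.template,
            "invert": self.invert,
        }


@dataclass(frozen=True)
class ClinicalRecord:
    """A subject's raw scale scores and binary diagnosis (PD=1, HC=0)."""

    subject_id: str
    scores: Mapping[str, float]
    diagnosis: int

    def validate(self, scale_defs: Mapping[str, ScaleDefinition]) -> None:
        missing = [sid for sid in scale_defs if sid not in self.scores]
        if missing:
            raise ValidationError(
                f"subject {self.subject_id}: missing scores for {missing}"
            )
        if self.diagnosis not in (0, 1):
            raise ValidationError(
                f"subject {self.subject_id}: diagnosis must be 0 or 1"
            )
        for sid, sdef in scale_defs.items():
            lo, hi = sdef.score_range
            s = self.scores[sid]
            if not (lo <= s <= hi):
                raise ScoreRangeError(
                    f"subject {self.subject_id}: {sid} score {s} outside [{lo}, {hi}]"
                )


@dataclass
class PromptSet:
    """Generated sentences and augmented variants for one subject."""

    subject_id: str
    sentences: dict[str, str]
    variants: dict[str, list[str]]
    n: int

    def __post_init__(self):
        for sid, vs in self.variants.items():
            if len(vs) != self.n:
                raise ValidationError(
                    f"{self.subject_id}/{sid}: expected {self.n} variants, got {len(vs)}"
                )
            if vs[0] != self.sentences[sid]:
                raise ValidationError(
                    f"{self.subject_id}/{sid}: variant 0 must be the template sentence"
                )

    @property
    def scale_ids(self) -> list[str]:
        return list(self.sentences)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "n": self.n,
            "sentences": dict(self.sentences),
            "variants": {k: list(v) for k, v in self.variants.items()},
        }


# --------------------------------------------------------------------------- io

def _scales_from_mapping(doc: dict) -> dict[str, ScaleDefinition]:
    if "scales" not in doc:
        raise ValidationError("scale file must contain a top-level 'scales' list")
    defs: dict[str, ScaleDefinition] = {}
    for entry in doc["scales"]:
        sdef = ScaleDefinition(
            scale_id=entry["scale_id"],
            score_range=tuple(entry["score_range"]),
            breakpoints=tuple(entry.get("breakpoints", ())),
            labels=tuple(entry.get("labels", DEFAULT_LABELS)),
            template=entry["template"],
            invert=bool(entry.get("invert", False)),
        )
        defs[sdef.scale_id] = sdef
    return defs


def load_scale_definitions(path=None) -> dict[str, ScaleDefinition]:
    """Load scale definitions from YAML; the shipped defaults when path is None."""
    if path is None:
        text = resources.files("modfus.data").joinpath("default_scales.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return _scales_from_mapping(yaml.safe_load(text))


def load_clinical_table(path, scale_defs: Mapping[str, ScaleDefinition]) -> list[ClinicalRecord]:
    """Read the cohort CSV (`subject_id,updrs,stai,ess,cdt,diagnosis`)."""
    df = pd.read_csv(path)
    required = {"subject_id", "diagnosis", *CSV_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        rec = ClinicalRecord(
            subject_id=str(row.subject_id),
            scores={sid: float(getattr(row, col)) for col, sid in CSV_COLUMNS.items()},
            diagnosis=int(row.diagnosis),
        )
        rec.validate(scale_defs)
        records.append(rec)
    return records


# ------------------------------------------------------------------ operations

def categorize_score(score: float, scale_def: ScaleDefinition) -> str:
    """Map a raw score to its severity label.

    Bins are half-open ``[b_{i-1}, b_i)``; the last bin is closed at the range
    maximum.  For inverted scales the bin order is reversed so that low scores
    yield the most severe label.
    """
    lo, hi = scale_def.score_range
    if not (lo <= score <= hi):
        raise ScoreRangeError(
            f"{scale_def.scale_id}: score {score} outside range [{lo}, {hi}]"
        )
    i = int(np.searchsorted(scale_def.breakpoints, score, side="right"))
    if scale_def.invert:
        i = len(scale_def.labels) - 1 - i
    return scale_def.labels[i]


def render_sentence(scale_def: ScaleDefinition, label: str) -> str:
    """Substitute a severity label into the scale's sentence template."""
    if label not in scale_def.labels:
        raise ValidationError(
            f"{scale_def.scale_id}: unknown label {label!r}; "
            f"expected one of {scale_def.labels}"
        )
    return scale_def.template.replace(PLACEHOLDER, label)


def _variant_seed(seed: int, subject_id: str, scale_id: str) -> int:
    h = hashlib.sha256(f"{seed}:{subject_id}:{scale_id}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def build_prompt_set(
    record: ClinicalRecord,
    scale_defs: Mapping[str, ScaleDefinition],
    n: int = 8,
    seed: int = 0,
    augmenter: Augmenter | None = None,
) -> PromptSet:
    """Generate the per-scale sentences and ``n`` augmented variants.

    Scales are emitted in the fixed order MDS-UPDRS, STAI, ESS, CDT (any
    additional configured scales follow, in definition order).  The result is
    a pure function of (record, scale_defs, n, seed).
    """
    record.validate(scale_defs)
    ordered = [sid for sid in SCALE_ORDER if sid in scale_defs]
    ordered += [sid for sid in scale_defs if sid not in ordered]
    sentences: dict[str, str] = {}
    variants: dict[str, list[str]] = {}
    for sid in ordered:
        sdef = scale_defs[sid]
        label = categorize_score(record.scores[sid], sdef)
        sent = render_sentence(sdef, label)
        sentences[sid] = sent
        variants[sid] = augment_sentence(
            sent, n, augmenter=augmenter, seed=_variant_seed(seed, record.subject_id, sid)
        )
    return PromptSet(record.subject_id, sentences, variants, n)


def sample_training_prompt(prompt_set: PromptSet, rng: np.random.Generator) -> str:
    """Join one uniformly sampled variant per scale into a single prompt.

    Scales keep their fixed order; with ``n == 1`` the result is the
    deterministic concatenation of the template sentences.
    """
    parts = []
    for sid in prompt_set.scale_ids:
        vs = prompt_set.variants[sid]
        parts.append(vs[int(rng.integers(len(vs)))])
    return " ".join(parts)
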