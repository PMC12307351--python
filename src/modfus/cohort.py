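"""Synthetic multimodal cohort simulator: clinical scores + brain phantoms.

Emulates the *structure* of a PD/HC neuroimaging-plus-scales cohort so every
pipeline stage runs without restricted data.  A single latent severity scalar
z drives both modalities, giving the cross-modal redundancy that contrastive
alignment assumes:

* scores:  x_j = μ_j + σ_j · s_j · (δ·d + √ρ·z + √(1−ρ)·ε_j), clipped to the
  scale range, where d is the diagnosis (PD=1), δ the standardised class
  shift (``score_effect``), ρ the latent coupling, and s_j = −1 for inverted
  scales (low clock-drawing score = impaired);
* volumes:  an ellipsoidal brain phantom with a spherical "lesion" region
  whose intensity is reduced by ``image_effect · (d + √ρ·z + √(1−ρ)·f)``,
  plus additive Gaussian voxel noise.

By construction the *within-class* correlation between a scale score and the
lesion-region contrast equals ρ (attenuated only by voxel noise); pooled
correlation additionally reflects the class main effects.  No anatomical
realism is attempted — the phantom exists to carry a class- and
severity-coupled regional signal.

Class imbalance defaults to the 234:149 PD:HC ratio of the cohort the
pipeline is modelled after, so stratified evaluation is exercised.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ValidationError
from .scales import (
    ClinicalRecord,
    PromptSet,
    ScaleDefinition,
    build_prompt_set,
    load_scale_definitions,
)

__all__ = [
    "CohortConfig",
    "SyntheticSubject",
    "MultimodalDataset",
    "simulate_record",
    "simulate_volume",
    "simulate_cohort",
    "generate_cohort",
    "load_cohort",
]

#: healthy-control score distributions (mean, sd) per scale — generator defaults
BASE_SCORE_PARAMS: dict[str, tuple[float, float]] = {
    "MDS-UPDRS": (5.0, 8.0),
    "STAI": (35.0, 10.0),
    "ESS": (6.0, 4.0),
    "CDT": (4.5, 1.0),
}


@dataclass(frozen=True)
class CohortConfig:
    n: int = 100
    pd_fraction: float = 234 / 383
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    score_effect: float = 1.0
    image_effect: float = 0.5
    lesion_center: tuple[float, float, float] | None = None  # voxel coords
    lesion_radius: float = 5.0
    noise_sd: float = 0.1
    coupling: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.pd_fraction < 1.0:
            raise ConfigError("pd_fraction must lie strictly between 0 and 1")
        if self.score_effect < 0 or self.image_effect < 0:
            raise ConfigError("effect sizes must be non-negative")
        if not 0.0 <= self.coupling <= 1.0:
            raise ConfigError("coupling must lie in [0, 1]")
        center = self.lesion_center
        if center is None:
            center = tuple(0.35 * s if i == 0 else 0.5 * s
                           for i, s in enumerate(self.volume_shape))
        center = tuple(float(c) for c in center)
        for c, s in zip(center, self.volume_shape):
            if not (self.lesion_radius <= c <= s - self.lesion_radius):
                raise ConfigError(
                    f"lesion (center {center}, radius {self.lesion_radius}) "
                    f"does not fit inside volume {self.volume_shape}"
                )
        object.__setattr__(self, "lesion_center", center)
        object.__setattr__(self, "volume_shape", tuple(int(s) for s in self.volume_shape))

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["volume_shape"] = list(self.volume_shape)
        d["lesion_center"] = list(self.lesion_center)
        return d


@dataclass
class SyntheticSubject:
    record: ClinicalRecord
    volume: np.ndarray
    latent: float  # severity latent z
    drive: float  # lesion drive d + √ρ·z + √(1−ρ)·f


@dataclass
class MultimodalDataset:
    """Aligned multimodal cohort: volumes, clinical records, labels, prompts.

    ``provenance`` carries the subject ids the dataset was built from, so
    downstream objects (vocabularies, pretrained encoders) can prove they
    never saw held-out subjects.
    """

    subject_ids: list[str]
    volumes: np.ndarray  # (n, X, Y, Z)
    records: list[ClinicalRecord]
    labels: np.ndarray  # (n,) int
    prompt_sets: list[PromptSet] | None = None
    config: CohortConfig | None = None
    provenance: frozenset = frozenset()

    def __post_init__(self):
        if not self.provenance:
            self.provenance = frozenset(self.subject_ids)

    def __len__(self) -> int:
        return len(self.subject_ids)

    def subset(self, indices) -> "MultimodalDataset":
        idx = np.asarray(indices)
        return MultimodalDataset(
            subject_ids=[self.subject_ids[i] for i in idx],
            volumes=self.volumes[idx],
            records=[self.records[i] for i in idx],
            labels=self.labels[idx],
            prompt_sets=None if self.prompt_sets is None
            else [self.prompt_sets[i] for i in idx],
            config=self.config,
            provenance=frozenset(self.subject_ids[i] for i in idx),
        )

    def with_prompts(self, scale_defs, n: int = 8, seed: int = 0,
                     augmenter=None) -> "MultimodalDataset":
        prompts = [
            build_prompt_set(rec, scale_defs, n=n, seed=seed, augmenter=augmenter)
            for rec in self.records
        ]
        return replace_dataset(self, prompt_sets=prompts)


def replace_dataset(ds: MultimodalDataset, **kw) -> MultimodalDataset:
    fields = dict(
        subject_ids=ds.subject_ids,
        volumes=ds.volumes,
        records=ds.records,
        labels=ds.labels,
        prompt_sets=ds.prompt_sets,
        config=ds.config,
        provenance=ds.provenance,
    )
    fields.update(kw)
    return MultimodalDataset(**fields)


# ------------------------------------------------------------------ simulation

def simulate_record(
    rng: np.random.Generator,
    diagnosis: int,
    config: CohortConfig,
    scale_defs: dict[str, ScaleDefinition],
    subject_id: str = "S000",
    latent: float | None = None,
) -> tuple[ClinicalRecord, float]:
    """Draw one subject's clinical record; returns (record, severity latent)."""
    z = float(rng.normal()) if latent is None else float(latent)
    w = np.sqrt(config.coupling)
    scores = {}
    for sid, sdef in scale_defs.items():
        mu, sd = BASE_SCORE_PARAMS.get(sid, (0.5 * sum(sdef.score_range), 1.0))
        eps = rng.normal()
        severity = config.score_effect * diagnosis + w * z + np.sqrt(1.0 - config.coupling) * eps
        sign = -1.0 if sdef.invert else 1.0
        lo, hi = sdef.score_range
        scores[sid] = float(np.clip(mu + sd * sign * severity, lo, hi))
    rec = ClinicalRecord(subject_id=subject_id, scores=scores, diagnosis=int(diagnosis))
    rec.validate(scale_defs)
    return rec, z


def _phantom_masks(config: CohortConfig):
    shape = config.volume_shape
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    center = [s / 2.0 - 0.5 for s in shape]
    radii = [0.42 * s for s in shape]
    brain = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii)) <= 1.0
    lc = config.lesion_center
    lesion = sum((g - c) ** 2 for g, c in zip(grids, lc)) <= config.lesion_radius**2
    return brain, lesion


def simulate_volume(
    rng: np.random.Generator,
    subject_latent: float,
    config: CohortConfig,
) -> np.ndarray:
    """Brain-phantom volume with severity-scaled lesion intensity reduction.

    ``subject_latent`` is the lesion drive (diagnosis + coupled severity
    noise); the lesion-region intensity is lowered by
    ``image_effect × subject_latent`` before Gaussian noise is added.
    """
    brain, lesion = _phantom_masks(config)
    vol = np.where(brain, 1.0, 0.0)
    vol = vol - np.where(lesion, config.image_effect * float(subject_latent), 0.0)
    if config.noise_sd > 0:
        vol = vol + rng.normal(0.0, config.noise_sd, size=config.volume_shape)
    return vol


def simulate_cohort(
    config: CohortConfig,
    scale_defs: dict[str, ScaleDefinition] | None = None,
) -> tuple[MultimodalDataset, list[SyntheticSubject]]:
    """Generate an in-memory cohort of exactly round(n·pd_fraction) PD subjects."""
    if scale_defs is None:
        scale_defs = load_scale_definitions()
    rng = np.random.default_rng(config.seed)
    n_pd = int(round(config.n * config.pd_fraction))
    if not 0 < n_pd < config.n:
        raise ConfigError("cohort must contain both classes; adjust n or pd_fraction")
    diagnoses = np.array([1] * n_pd + [0] * (config.n - n_pd))
    rng.shuffle(diagnoses)
    w = np.sqrt(config.coupling)
    subjects: list[SyntheticSubject] = []
    for i, d in enumerate(diagnoses):
        sid = f"S{i:04d}"
        rec, z = simulate_record(rng, int(d), config, scale_defs, subject_id=sid)
        f = rng.normal()
        drive = float(d) + w * z + np.sqrt(1.0 - config.coupling) * f
        vol = simulate_volume(rng, drive, config)
        subjects.append(SyntheticSubject(rec, vol, z, drive))
    ds = MultimodalDataset(
        subject_ids=[s.record.subject_id for s in subjects],
        volumes=np.stack([s.volume for s in subjects]),
        records=[s.record for s in subjects],
        labels=np.array([s.record.diagnosis for s in subjects], dtype=int),
        config=config,
    )
    return ds, subjects


# ------------------------------------------------------------------------- io

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def generate_cohort(
    config: CohortConfig,
    out_dir,
    scale_defs: dict[str, ScaleDefinition] | None = None,
) -> MultimodalDataset:
    """Write a cohort to disk: NIfTI volume per subject, cohort.csv, manifest.json."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, _ = simulate_cohort(config, scale_defs)
    files = {}
    for sid, vol in zip(ds.subject_ids, ds.volumes):
        path = out / f"{sid}.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4)), path)
        files[path.name] = _sha256(path)
    rows = []
    for rec in ds.records:
        rows.append(
            {
                "subject_id": rec.subject_id,
                "updrs": rec.scores["MDS-UPDRS"],
                "stai": rec.scores["STAI"],
                "ess": rec.scores["ESS"],
                "cdt": rec.scores["CDT"],
                "diagnosis": rec.diagnosis,
            }
        )
    csv_path = out / "cohort.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    files[csv_path.name] = _sha256(csv_path)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_pd": int(ds.labels.sum()),
        "n_hc": int((1 - ds.labels).sum()),
        "checksums": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ds


def load_cohort(
    data_dir,
    scale_defs: dict[str, ScaleDefinition] | None = None,
) -> MultimodalDataset:
    """Read a generated cohort directory back into memory."""
    import nibabel as nib

    from .scales import load_clinical_table

    if scale_defs is None:
        scale_defs = load_scale_definitions()
    data_dir = Path(data_dir)
    records = load_clinical_table(data_dir / "cohort.csv", scale_defs)
    volumes = []
    for rec in records:
        path = data_dir / f"{rec.subject_id}.nii.gz"
        if not path.exists():
            raise ValidationError(f"missing volume for subject {rec.subject_id}")
        volumes.append(np.asarray(nib.load(path).get_fdata(), dtype=np.float64))
    config = None
    manifest = data_dir / "manifest.json"
    if manifest.exists():
        raw = json.loads(manifest.read_text())["config"]
        raw["volume_shape"] = tuple(raw["volume_shape"])
        raw["lesion_center"] = tuple(raw["lesion_center"])
        config = CohortConfig(**raw)
    return MultimodalDataset(
        subject_ids=[r.subject_id for r in records],
        volumes=np.stack(volumes),
        records=records,
        labels=np.array([r.diagnosis for r in records], dtype=int),
        config=config,
    )
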