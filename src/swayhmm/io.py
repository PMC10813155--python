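"""Reading, writing and preprocessing COP recordings and cohort manifests.

File dialect (fixed so round trips are bit-exact):

* COP recording: CSV with header ``time,ML,AP`` (or a single-channel subset),
  time in seconds from 0, displacements in millimeters, one row per sample.
* Cohort manifest: CSV with header ``subject_id,path,label[,group]``; label is
  ``healthy`` or ``pd``; paths are resolved relative to the manifest.

Preprocessing defaults to the identity (no decimation, no centering): the
classification approach operates on raw stabilometric signals.  Decimation
exists purely to trade sampling rate for speed and is opt-in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import (
    CopFileError,
    ManifestError,
    MissingColumnError,
    NaNValueError,
    NonMonotoneTimeError,
    SamplingRateError,
)
from .hmm import (
    GaussianHMM,
    GaussianMixtureEmission,
    MarkovChainParams,
    ObservationSequence,
)

VALID_LABELS = ("healthy", "pd")
CHANNEL_ORDER = ("ML", "AP")


@dataclass
class ManifestRecord:
    subject_id: str
    path: str
    label: str
    group: Optional[str] = None


@dataclass
class CohortManifest:
    """Index of a cohort: one record per subject plus recording metadata."""

    records: List[ManifestRecord] = field(default_factory=list)
    sampling_rate_hz: Optional[float] = None
    duration_s: Optional[float] = None

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ManifestError(f"duplicate subject_id(s): {sorted(dupes)}")
        for r in self.records:
            if r.label not in VALID_LABELS:
                raise ManifestError(
                    f"subject {r.subject_id!r}: unknown label {r.label!r} "
                    f"(expected one of {VALID_LABELS})"
                )

    def __len__(self) -> int:
        return len(self.records)


def read_cop_file(
    path, expected_rate: Optional[float] = None
) -> ObservationSequence:
    """Load one recording; infers the sampling rate from the time column and
    checks it against ``expected_rate`` within 1% when given."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise CopFileError(f"cannot parse {path}: {exc}") from exc
    if "time" not in df.columns:
        raise MissingColumnError(f"{path}: no 'time' column (found {list(df.columns)})")
    channels = tuple(c for c in CHANNEL_ORDER if c in df.columns)
    if not channels:
        raise MissingColumnError(
            f"{path}: need at least one of {CHANNEL_ORDER}, found {list(df.columns)}"
        )
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise CopFileError(f"{path}: need at least 2 samples to infer a rate")
    if np.any(np.isnan(df[list(channels)].to_numpy())) or np.any(np.isnan(t)):
        raise NaNValueError(f"{path}: NaN values present")
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise NonMonotoneTimeError(
            f"{path}: time not strictly increasing at row {i + 1}"
        )
    rate = 1.0 / float(np.median(dt))
    if expected_rate is not None and abs(rate - expected_rate) > 0.01 * expected_rate:
        raise SamplingRateError(
            f"{path}: inferred rate {rate:.6g} Hz differs from expected "
            f"{expected_rate:.6g} Hz by more than 1%"
        )
    return ObservationSequence(
        values=df[list(channels)].to_numpy(dtype=float),
        sampling_rate_hz=rate,
        channels=channels,
        subject_id=path.stem,
    )


def write_cop_file(seq: ObservationSequence, path) -> Path:
    """Write a recording as ``time,<channels>`` CSV; round-trip safe."""
    path = Path(path)
    t = np.arange(seq.n) / seq.sampling_rate_hz
    df = pd.DataFrame({"time": t})
    for i, ch in enumerate(seq.channels):
        df[ch] = seq.values[:, i]
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")  # bit-exact round trip
    return path


def read_manifest(path) -> CohortManifest:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise ManifestError(f"cannot parse manifest {path}: {exc}") from exc
    required = {"subject_id", "path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"{path}: manifest missing column(s) {sorted(missing)}")
    if len(df) == 0:
        raise ManifestError(f"{path}: manifest is empty")
    records = [
        ManifestRecord(
            subject_id=row.subject_id,
            path=row.path,
            label=row.label,
            group=getattr(row, "group", None),
        )
        for row in df.itertuples(index=False)
    ]
    return CohortManifest(records=records)


def write_manifest(manifest: CohortManifest, path) -> Path:
    path = Path(path)
    rows = [
        {
            "subject_id": r.subject_id,
            "path": r.path,
            "label": r.label,
            **({"group": r.group} if r.group is not None else {}),
        }
        for r in manifest.records
    ]
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def load_cohort(
    manifest: CohortManifest,
    base_dir=None,
    expected_rate: Optional[float] = None,
) -> Tuple[List[ObservationSequence], List[ObservationSequence]]:
    """Load every referenced file; returns (healthy list, pd list)."""
    base = Path(base_dir) if base_dir is not None else Path(".")
    healthy, pd_list = [], []
    rate = expected_rate if expected_rate is not None else manifest.sampling_rate_hz
    for r in manifest.records:
        p = Path(r.path)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise ManifestError(
                f"subject {r.subject_id!r}: file not found: {p}"
            )
        seq = read_cop_file(p, expected_rate=rate)
        seq.subject_id = r.subject_id
        seq.label = r.label
        (healthy if r.label == "healthy" else pd_list).append(seq)
    return healthy, pd_list


def preprocess(
    seq: ObservationSequence, decimate_factor: int = 1, center: bool = False
) -> ObservationSequence:
    """Keep every ``decimate_factor``-th sample and optionally subtract the
    per-channel mean.  The default (1, False) returns the input unchanged."""
    if not float(decimate_factor).is_integer() or decimate_factor < 1:
        raise ValueError(
            f"decimate_factor must be an integer >= 1, got {decimate_factor}"
        )
    decimate_factor = int(decimate_factor)
    if decimate_factor == 1 and not center:
        return seq
    values = seq.values[::decimate_factor]
    if center:
        values = values - values.mean(axis=0)
    return ObservationSequence(
        values=values,
        sampling_rate_hz=seq.sampling_rate_hz / decimate_factor,
        channels=seq.channels,
        subject_id=seq.subject_id,
        label=seq.label,
    )


# ---------------------------------------------------------------------------
# Model serialization (versioned, human-readable JSON)
# ---------------------------------------------------------------------------

MODEL_SCHEMA = "swayhmm-model/1"


def _hmm_to_dict(model: GaussianHMM) -> dict:
    return {
        "K": model.chain.K,
        "order": model.chain.order,
        "d": model.d,
        "pi": model.chain.pi.tolist(),
        "A": model.chain.A.tolist(),
        "emissions": [
            {
                "weights": e.weights.tolist(),
                "means": e.means.tolist(),
                "covariances": e.covariances.tolist(),
            }
            for e in model.emissions
        ],
    }


def _hmm_from_dict(data: dict) -> GaussianHMM:
    chain = MarkovChainParams(
        K=data["K"],
        A=np.array(data["A"]),
        pi=np.array(data["pi"]),
        order=data.get("order", 1),
    )
    emissions = [
        GaussianMixtureEmission(
            weights=np.array(e["weights"]),
            means=np.array(e["means"]),
            covariances=np.array(e["covariances"]),
        )
        for e in data["emissions"]
    ]
    return GaussianHMM(chain=chain, d=data["d"], emissions=emissions)


def save_classifier(model, path) -> Path:
    """Serialize a trained two-model classifier to versioned JSON."""
    from .classify import ClassifierModel  # local import to avoid a cycle

    assert isinstance(model, ClassifierModel)
    cfg = model.config
    payload = {
        "schema": MODEL_SCHEMA,
        "config": {
            "channel_mode": cfg.channel_mode,
            "channel_fusion": cfg.channel_fusion,
            "decimate_factor": cfg.decimate_factor,
            "center": cfg.center,
            "fit": vars(cfg.fit_config).copy(),
        },
        "h_model": [_hmm_to_dict(m) for m in model.h_models],
        "pd_model": [_hmm_to_dict(m) for m in model.pd_models],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_classifier(path):
    from .classify import ClassifierConfig, ClassifierModel
    from .learn import FitConfig

    data = json.loads(Path(path).read_text())
    if data.get("schema") != MODEL_SCHEMA:
        raise CopFileError(
            f"{path}: unknown model schema {data.get('schema')!r} "
            f"(expected {MODEL_SCHEMA})"
        )
    c = data["config"]
    config = ClassifierConfig(
        channel_mode=c["channel_mode"],
        channel_fusion=c["channel_fusion"],
        decimate_factor=c["decimate_factor"],
        center=c["center"],
        fit_config=FitConfig(**c["fit"]),
    )
    return ClassifierModel(
        h_models=[_hmm_from_dict(m) for m in data["h_model"]],
        pd_models=[_hmm_from_dict(m) for m in data["pd_model"]],
        config=config,
    )
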