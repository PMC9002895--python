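"""Dataset building, experiment orchestration, caching, and model scorers.

``build_dataset`` turns a source (synthetic plan or a directory of WFDB
records) into paired two-lead training items — spectrogram image plus raw
handcrafted feature vector per lead — balanced 50–50 and split 90/10.
``run_experiment`` trains one merged model per lead, evaluates the fused
predictions on the test split, and emits a result row (TP/FP/TN/FN plus
SEN/FAR/PPV/ACC).  Built datasets are cached on disk keyed by a content hash
of the configuration, so an unchanged re-run loads instead of recomputing.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .core import ECGRecord, Heartbeat, Segment
from .evaluate import confusion, metrics
from .features import (HEARTBEAT_FEATURE_NAMES, RHYTHM_FEATURE_NAMES,
                       FeatureScaler, fit_scaler, heartbeat_features,
                       rhythm_features)
from .model import ModelConfig, MergedModel, build_model, fuse_leads, train
from .preprocess import (balance_and_split, extract_heartbeats,
                         normalized_record, slide_rhythm_windows)
from .spectrogram import HEARTBEAT_WINDOW_LEN, RHYTHM_WINDOW_LEN, render, stft
from .synth import SynthParams, expected_beat_count, generate_dataset
from .wfdb_io import LabelMap, read_record

__all__ = ["RunConfig", "Dataset", "build_dataset", "run_experiment",
           "ModelScorer", "synthetic_source", "segment_input", "beat_input"]


@dataclass
class RunConfig:
    """Everything one experiment needs, in one place."""

    kind: str = "rhythm"                      # "rhythm" or "beat"
    wfdb_dir: str | None = None               # read records here if set ...
    n_records: int = 16                       # ... else synthesize this many
    record_seconds: float = 30.0
    abnormal_frac: float = 0.5
    noise_sd: float = 0.02
    model: ModelConfig = field(default_factory=ModelConfig)
    mode: str = "gray"
    window_len: int | None = None             # STFT L; default by kind
    hop: int | None = None
    train_frac: float = 0.9
    label_map: LabelMap = field(default_factory=LabelMap)
    outdir: str = "runs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("rhythm", "beat"):
            raise ValueError("kind must be 'rhythm' or 'beat'")
        if self.window_len is None:
            self.window_len = RHYTHM_WINDOW_LEN if self.kind == "rhythm" else HEARTBEAT_WINDOW_LEN
        n_feat = 9 if self.kind == "rhythm" else 11
        if self.model.n_handcrafted != n_feat or self.model.input_mode != self.mode:
            self.model = replace(self.model, n_handcrafted=n_feat, input_mode=self.mode)

    def cache_key(self) -> str:
        d = asdict(self)
        d["label_map"] = {k: sorted(v) if isinstance(v, frozenset) else v
                          for k, v in d["label_map"].items()}
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class Dataset:
    """Paired two-lead items: ``images[lead]`` is (N, C, H, W), ``feats[lead]``
    the *raw* handcrafted vectors; scalers are fit on the training split."""

    train_images: list[np.ndarray]
    train_feats: list[np.ndarray]
    train_labels: np.ndarray
    test_images: list[np.ndarray]
    test_feats: list[np.ndarray]
    test_labels: np.ndarray
    scalers: list[FeatureScaler]
    manifest: dict
    from_cache: bool = False


def synthetic_source(kind: str, n_records: int, record_seconds: float,
                     abnormal_frac: float = 0.5, noise_sd: float = 0.02) -> list[SynthParams]:
    """A parameter grid emulating the study conditions at desk scale.

    Normal records are NSR at 60–80 bpm.  Abnormal rhythm records are
    tachycardic (160 bpm) ventricular-tachycardia spans with wide-QRS beats;
    abnormal beat records are NSR with premature / wide-QRS / absent-P beats
    scattered through them.
    """
    grid: list[SynthParams] = []
    normal_rates = (60.0, 70.0, 80.0)
    period = max(1, int(round(1.0 / abnormal_frac))) if abnormal_frac > 0 else 0
    for i in range(n_records):
        abnormal = period > 0 and i % period == period - 1
        if not abnormal:
            grid.append(SynthParams(duration=record_seconds, fs=250,
                                    heart_rate=normal_rates[i % 3], noise_sd=noise_sd))
        elif kind == "rhythm":
            hr = 160.0
            n_beats = expected_beat_count(record_seconds, 250, hr)
            grid.append(SynthParams(
                duration=record_seconds, fs=250, heart_rate=hr, noise_sd=noise_sd,
                anomaly_plan=[{"beat_index": b, "kind": "wide_qrs"} for b in range(n_beats)],
                rhythm_plan=[{"start_beat": 0, "end_beat": n_beats - 1, "symbol": "VT"}],
            ))
        else:
            hr = normal_rates[i % 3]
            n_beats = expected_beat_count(record_seconds, 250, hr)
            kinds = ("premature", "wide_qrs", "absent_p")
            plan = [{"beat_index": b, "kind": kinds[(b // 3) % 3]}
                    for b in range(2, n_beats - 2, 3)]
            grid.append(SynthParams(duration=record_seconds, fs=250, heart_rate=hr,
                                    noise_sd=noise_sd, anomaly_plan=plan))
    return grid


def segment_input(segment: Segment, cfg: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """(image (C, H, W) in [0, 1], raw 9-dim feature vector) for one window."""
    mat = stft(segment.samples, L=cfg.window_len, hop=cfg.hop, fs=segment.fs)
    h, w = cfg.model.input_hw
    img = render(mat, mode=cfg.mode, height=h, width=w)
    return img.transpose(2, 0, 1).astype(float) / 255.0, rhythm_features(segment)


def beat_input(beat: Heartbeat, cfg: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """(image, raw 11-dim feature vector) for one heartbeat excerpt."""
    mat = stft(beat.samples, L=cfg.window_len, hop=cfg.hop, fs=beat.fs)
    h, w = cfg.model.input_hw
    img = render(mat, mode=cfg.mode, height=h, width=w)
    return img.transpose(2, 0, 1).astype(float) / 255.0, heartbeat_features(beat)


def _source_records(cfg: RunConfig) -> list[ECGRecord]:
    if cfg.wfdb_dir:
        headers = sorted(Path(cfg.wfdb_dir).glob("*.hea"))
        if not headers:
            raise ValueError(f"no WFDB records found in {cfg.wfdb_dir}")
        return [read_record(h.with_suffix("")) for h in headers]
    grid = synthetic_source(cfg.kind, cfg.n_records, cfg.record_seconds,
                            cfg.abnormal_frac, cfg.noise_sd)
    return generate_dataset(cfg.n_records, grid, seed=cfg.seed)


def _paired_items(cfg: RunConfig, records: list[ECGRecord]):
    """Per-item ((img, feat) per lead, label) with both leads paired."""
    items, labels = [], []
    for rec in records:
        nrec = normalized_record(rec)
        if cfg.kind == "rhythm":
            per_lead = [slide_rhythm_windows(nrec, lead, cfg.label_map)
                        for lead in range(len(nrec.leads))]
            maker = segment_input
        else:
            per_lead = [extract_heartbeats(nrec, lead, cfg.label_map)
                        for lead in range(len(nrec.leads))]
            maker = beat_input
        for pair in zip(*per_lead):
            if cfg.kind == "beat":
                if pair[0].symbol in cfg.label_map.beat_excluded:
                    continue
                if len(pair[0].samples) < cfg.window_len:
                    continue
            items.append(tuple(maker(x, cfg) for x in pair))
            labels.append(pair[0].label)
    return items, labels


def build_dataset(cfg: RunConfig) -> Dataset:
    """Build (or load from cache) the balanced, split, featurized dataset."""
    cache_dir = Path(cfg.outdir) / "cache"
    key = cfg.cache_key()
    npz_path = cache_dir / f"{key}.npz"
    manifest_path = cache_dir / f"{key}.json"
    if npz_path.exists() and manifest_path.exists():
        return _load_cached(npz_path, manifest_path)

    records = _source_records(cfg)
    items, labels = _paired_items(cfg, records)
    if not items:
        raise ValueError("empty dataset source")
    train, test = balance_and_split(items, labels, cfg.train_frac, seed=cfg.seed)

    def unpack(split):
        imgs = [np.stack([it[lead][0] for it, _ in split]) for lead in range(2)]
        feats = [np.stack([it[lead][1] for it, _ in split]) for lead in range(2)]
        labels = np.array([lab for _, lab in split])
        return imgs, feats, labels

    tr_imgs, tr_feats, tr_labels = unpack(train)
    te_imgs, te_feats, te_labels = unpack(test)
    scalers = [fit_scaler(tr_feats[lead]) for lead in range(2)]

    manifest = {
        "cache_key": key,
        "kind": cfg.kind,
        "n_records": len(records),
        "n_items": len(items),
        "class_counts": {"normal": int(np.sum(np.array(labels) == 0)),
                         "abnormal": int(np.sum(np.array(labels) == 1))},
        "train_size": len(train),
        "test_size": len(test),
        "train_class_counts": {"normal": int(np.sum(tr_labels == 0)),
                               "abnormal": int(np.sum(tr_labels == 1))},
        "test_class_counts": {"normal": int(np.sum(te_labels == 0)),
                              "abnormal": int(np.sum(te_labels == 1))},
        "feature_names": list(RHYTHM_FEATURE_NAMES if cfg.kind == "rhythm"
                              else HEARTBEAT_FEATURE_NAMES),
        "seed": cfg.seed,
    }

    cache_dir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        npz_path,
        tr_img0=tr_imgs[0], tr_img1=tr_imgs[1],
        tr_feat0=tr_feats[0], tr_feat1=tr_feats[1], tr_labels=tr_labels,
        te_img0=te_imgs[0], te_img1=te_imgs[1],
        te_feat0=te_feats[0], te_feat1=te_feats[1], te_labels=te_labels,
        scaler0_min=scalers[0].mins, scaler0_max=scalers[0].maxs,
        scaler1_min=scalers[1].mins, scaler1_max=scalers[1].maxs,
    )
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return Dataset(tr_imgs, tr_feats, tr_labels, te_imgs, te_feats, te_labels,
                   scalers, manifest, from_cache=False)


def _load_cached(npz_path: Path, manifest_path: Path) -> Dataset:
    z = np.load(npz_path)
    scalers = [FeatureScaler(z["scaler0_min"], z["scaler0_max"]),
               FeatureScaler(z["scaler1_min"], z["scaler1_max"])]
    return Dataset(
        [z["tr_img0"], z["tr_img1"]], [z["tr_feat0"], z["tr_feat1"]], z["tr_labels"],
        [z["te_img0"], z["te_img1"]], [z["te_feat0"], z["te_feat1"]], z["te_labels"],
        scalers, json.loads(manifest_path.read_text()), from_cache=True,
    )


def run_experiment(cfg: RunConfig) -> dict:
    """Train per-lead models, evaluate fused predictions on the test split.

    Returns a result row: confusion counts, the four metrics (display-rounded
    and full precision), training histories, and the reproducibility manifest.
    """
    t0 = time.time()
    ds = build_dataset(cfg)
    models, histories = [], []
    for lead in range(2):
        mcfg = replace(cfg.model, seed=cfg.model.seed + 1000 * lead)
        model = build_model(mcfg)
        scaled = ds.scalers[lead].transform(ds.train_feats[lead])
        histories.append(train(model, ds.train_images[lead], scaled,
                               ds.train_labels, mcfg))
        models.append(model)

    fused_labels = []
    scores = []
    for lead in range(2):
        scaled = ds.scalers[lead].transform(ds.test_feats[lead])
        scores.append(models[lead].forward(ds.test_images[lead], scaled, train=False))
    for y1, y2 in zip(*scores):
        fused_labels.append(fuse_leads(float(y1), float(y2)).label)

    counts = confusion(fused_labels, ds.test_labels)
    mets = metrics(counts)
    row = {
        "kind": cfg.kind, "backbone": cfg.model.backbone, "mode": cfg.mode,
        "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
        **mets.rounded(),
        "full_precision": {"sen": mets.sen, "far": mets.far,
                           "ppv": mets.ppv, "acc": mets.acc},
        "wall_time_s": round(time.time() - t0, 2),
        "epochs": [h["epochs_run"] for h in histories],
        "manifest": ds.manifest,
        "seed": cfg.seed,
    }
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / f"result-{cfg.kind}-{cfg.cache_key()}.json").write_text(
        json.dumps(row, indent=2, default=float))
    row["models"] = models
    row["histories"] = histories
    return row


class ModelScorer:
    """Per-lead scoring callable for :func:`ecgfusion.evaluate.detect_anomalies`.

    Wraps a trained merged model with its feature scaler and featurization so
    it can score a :class:`Segment` or :class:`Heartbeat` directly.
    """

    def __init__(self, model: MergedModel, scaler: FeatureScaler, cfg: RunConfig):
        self.model, self.scaler, self.cfg = model, scaler, cfg

    def __call__(self, item: Segment | Heartbeat) -> float:
        maker = segment_input if isinstance(item, Segment) else beat_input
        img, feat = maker(item, self.cfg)
        scaled = np.atleast_2d(self.scaler.transform(feat))
        return float(self.model.forward(img[None], scaled, train=False)[0])
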