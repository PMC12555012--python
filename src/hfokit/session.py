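"""Result persistence, annotation records, and the quick-detect pipeline.

A :class:`ResultArchive` bundles everything one detection run produces —
recording metadata, config snapshots, the event list, optional cascade
results and reviewer annotations — and round-trips losslessly through a
versioned NPZ container (arrays + a JSON metadata member).  The same content
exports to a spreadsheet with one row per event, and :func:`quick_detect`
chains load → filter → detect → optional classify → optional export exactly
as calling the stages by hand.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from hfokit import __version__ as _tool_version
from hfokit.classify import ClassificationResult, InferenceConfig, run_cascade
from hfokit.detect import Event, EventList, run_detector
from hfokit.eeg_io import FilterSpec, Recording, apply_filters, read_edf
from hfokit.features import TFRConfig, event_tfr, to_model_input

logger = logging.getLogger(__name__)

__all__ = [
    "LABEL_VOCABULARY", "AnnotationRecord", "ResultArchive",
    "save_archive", "load_archive", "export_spreadsheet", "import_spreadsheet",
    "annotate_event", "quick_detect",
]

LABEL_VOCABULARY = ("artifact", "hfo", "spk_hfo", "ehfo", "unreviewed")
_ARCHIVE_VERSION = 1

# display color codes of the event categories (metadata only, never rendered)
CATEGORY_COLORS = {"artifact": "orange", "spk_hfo": "purple", "hfo": "green"}


@dataclass
class AnnotationRecord:
    """Reviewer decision for one event (index into the archive's EventList)."""

    event_index: int
    suggested_label: str = "unreviewed"
    accepted_label: str = "unreviewed"
    reviewer: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.accepted_label not in LABEL_VOCABULARY:
            raise ValueError(
                f"label {self.accepted_label!r} not in vocabulary {LABEL_VOCABULARY}")


@dataclass
class ResultArchive:
    """Everything a detection/classification run produced, ready to persist."""

    recording_meta: dict
    filter_config: dict
    events: EventList
    classification: Optional[ClassificationResult] = None
    annotations: list[AnnotationRecord] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)
    version: int = _ARCHIVE_VERSION
    tool_version: str = _tool_version

    def __post_init__(self) -> None:
        for ann in self.annotations:
            if not 0 <= ann.event_index < len(self.events):
                raise ValueError(
                    f"annotation references event {ann.event_index}, but the archive "
                    f"holds {len(self.events)} events")


# ---------------------------------------------------------------------------
# NPZ container


def save_archive(archive: ResultArchive, path: str | Path) -> Path:
    path = Path(path)
    ev = archive.events
    meta = {
        "version": archive.version,
        "tool_version": archive.tool_version,
        "recording_meta": archive.recording_meta,
        "filter_config": archive.filter_config,
        "detector": ev.detector,
        "detector_config": ev.config,
        "recording_id": ev.recording_id,
        "eventlist_meta": ev.meta,
        "history": archive.history,
        "category_colors": CATEGORY_COLORS,
        "has_classification": archive.classification is not None,
    }
    arrays: dict[str, np.ndarray] = {
        "meta_json": np.array(json.dumps(meta)),
        "event_channel": np.array([e.channel for e in ev], dtype="U64"),
        "event_start": np.array([e.start for e in ev], dtype=np.int64),
        "event_end": np.array([e.end for e in ev], dtype=np.int64),
        "event_fs": np.array([e.fs for e in ev], dtype=np.float64),
        "ann_event_index": np.array([a.event_index for a in archive.annotations], dtype=np.int64),
        "ann_suggested": np.array([a.suggested_label for a in archive.annotations], dtype="U16"),
        "ann_accepted": np.array([a.accepted_label for a in archive.annotations], dtype="U16"),
        "ann_reviewer": np.array([a.reviewer for a in archive.annotations], dtype="U64"),
        "ann_timestamp": np.array([a.timestamp for a in archive.annotations], dtype="U40"),
    }
    cls = archive.classification
    if cls is not None:
        arrays["p_artifact"] = cls.p_artifact.astype(np.float64)
        arrays["label_artifact"] = cls.label_artifact.astype(np.int8)
        for role in ("spk", "ehfo"):
            p = getattr(cls, f"p_{role}")
            if p is not None:
                arrays[f"p_{role}"] = p.astype(np.float64)
                arrays[f"label_{role}"] = getattr(cls, f"label_{role}").astype(np.int8)
    with open(path, "wb") as fh:  # exact path, no implicit .npz suffixing
        np.savez(fh, **arrays)
    return path


def load_archive(path: str | Path) -> ResultArchive:
    path = Path(path)
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta_json"]))
        if meta.get("version") != _ARCHIVE_VERSION:
            raise ValueError(
                f"archive version {meta.get('version')} is incompatible with this "
                f"release (expects {_ARCHIVE_VERSION}); migrate the archive first")
        fs_arr = npz["event_fs"]
        events = [Event(str(c), int(s), int(e), fs=float(f))
                  for c, s, e, f in zip(npz["event_channel"], npz["event_start"],
                                        npz["event_end"], fs_arr)]
        event_list = EventList(recording_id=meta["recording_id"], detector=meta["detector"],
                               config=meta["detector_config"], events=events,
                               meta=meta.get("eventlist_meta", {}))
        classification = None
        if meta.get("has_classification"):
            kwargs = {
                "p_artifact": npz["p_artifact"],
                "label_artifact": npz["label_artifact"].astype(bool),
            }
            for role in ("spk", "ehfo"):
                if f"p_{role}" in npz.files:
                    kwargs[f"p_{role}"] = npz[f"p_{role}"]
                    kwargs[f"label_{role}"] = npz[f"label_{role}"].astype(bool)
            classification = ClassificationResult(**kwargs)
        annotations = [
            AnnotationRecord(event_index=int(i), suggested_label=str(sg),
                             accepted_label=str(ac), reviewer=str(rv), timestamp=str(ts))
            for i, sg, ac, rv, ts in zip(npz["ann_event_index"], npz["ann_suggested"],
                                         npz["ann_accepted"], npz["ann_reviewer"],
                                         npz["ann_timestamp"])]
    return ResultArchive(recording_meta=meta["recording_meta"],
                         filter_config=meta["filter_config"], events=event_list,
                         classification=classification, annotations=annotations,
                         history=meta.get("history", []), version=meta["version"],
                         tool_version=meta.get("tool_version", ""))


# ---------------------------------------------------------------------------
# Spreadsheet


_SHEET_COLUMNS = ["event_index", "channel", "start_s", "end_s", "duration_s",
                  "p_artifact", "label_artifact", "p_spk", "label_spk",
                  "p_ehfo", "label_ehfo", "accepted_label"]


def archive_to_frame(archive: ResultArchive) -> pd.DataFrame:
    ev = archive.events
    n = len(ev)
    accepted = ["unreviewed"] * n
    for ann in archive.annotations:
        accepted[ann.event_index] = ann.accepted_label
    cls = archive.classification

    def col(name, fmt=float):
        if cls is None:
            return [np.nan] * n
        arr = getattr(cls, name)
        return [np.nan] * n if arr is None else [fmt(v) for v in arr]

    frame = pd.DataFrame({
        "event_index": range(n),
        "channel": [e.channel for e in ev],
        "start_s": [e.start_s for e in ev],
        "end_s": [e.end_s for e in ev],
        "duration_s": [e.duration_s for e in ev],
        "p_artifact": col("p_artifact"),
        "label_artifact": col("label_artifact", bool),
        "p_spk": col("p_spk"),
        "label_spk": col("label_spk", bool),
        "p_ehfo": col("p_ehfo"),
        "label_ehfo": col("label_ehfo", bool),
        "accepted_label": accepted,
    }, columns=_SHEET_COLUMNS)
    return frame


def export_spreadsheet(archive: ResultArchive, path: str | Path) -> Path:
    """One row per event, fixed column order, XLSX workbook."""
    path = Path(path)
    frame = archive_to_frame(archive)
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        frame.to_excel(writer, index=False, sheet_name="events")
    return path


def import_spreadsheet(path: str | Path, fs: float, detector: str = "imported") -> EventList:
    """Reconstruct the EventList intervals from an exported sheet."""
    frame = pd.read_excel(path, sheet_name="events")
    events = [Event(str(r.channel), int(round(r.start_s * fs)), int(round(r.end_s * fs)), fs=fs)
              for r in frame.itertuples()]
    return EventList(recording_id="", detector=detector, config={}, events=events)


# ---------------------------------------------------------------------------
# Annotation


def annotate_event(archive: ResultArchive, event_index: int, label: str,
                   reviewer: str = "") -> ResultArchive:
    """Record a reviewer label for one event; re-annotation overwrites it.

    ``suggested_label`` (from the classifier) is never touched; every call
    appends an audit entry to ``archive.history``.
    """
    if label not in LABEL_VOCABULARY:
        raise ValueError(f"unknown label {label!r}; valid labels: {LABEL_VOCABULARY}")
    if not 0 <= event_index < len(archive.events):
        raise IndexError(f"event index {event_index} out of range 0..{len(archive.events) - 1}")
    stamp = datetime.now(timezone.utc).isoformat()
    existing = next((a for a in archive.annotations if a.event_index == event_index), None)
    if existing is None:
        suggested = _suggested_label(archive, event_index)
        archive.annotations.append(AnnotationRecord(
            event_index=event_index, suggested_label=suggested, accepted_label=label,
            reviewer=reviewer, timestamp=stamp))
    else:
        existing.accepted_label = label
        existing.reviewer = reviewer
        existing.timestamp = stamp
    archive.history.append({"event_index": event_index, "accepted_label": label,
                            "reviewer": reviewer, "timestamp": stamp})
    return archive


def _suggested_label(archive: ResultArchive, i: int) -> str:
    cls = archive.classification
    if cls is None:
        return "unreviewed"
    if cls.label_artifact[i]:
        return "artifact"
    if cls.label_ehfo is not None and cls.label_ehfo[i]:
        return "ehfo"
    if cls.label_spk is not None and cls.label_spk[i]:
        return "spk_hfo"
    return "hfo"


# ---------------------------------------------------------------------------
# Quick-detect pipeline


def quick_detect(input_path: str | Path,
                 filter_spec: FilterSpec,
                 detector_name: str,
                 detector_cfg=None,
                 classify_models: Optional[dict] = None,
                 inference_cfg: Optional[InferenceConfig] = None,
                 tfr_cfg: Optional[TFRConfig] = None,
                 out_path: Optional[str | Path] = None,
                 xlsx_path: Optional[str | Path] = None,
                 n_jobs: int = 1) -> ResultArchive:
    """Load → filter → detect → optionally classify → optionally export.

    Equivalent to composing the stages by hand: the recording is read from
    EDF, filtered per ``filter_spec``, the named detector runs on the
    filtered recording, and (if requested) event images are computed from the
    loaded raw recording and pushed through the cascade.  Errors are raised
    with the failing stage named; a classification request without an
    artifact model fails before any detection work starts.
    """
    if classify_models is not None and classify_models.get("artifact") is None:
        raise ValueError("classification stage: cascade requires an artifact model "
                         "(checked before detection so no work is discarded)")
    try:
        rec = read_edf(input_path)
    except Exception as exc:
        raise type(exc)(f"load stage: {exc}") from exc
    try:
        filtered = apply_filters(rec, filter_spec)
    except Exception as exc:
        raise type(exc)(f"filter stage: {exc}") from exc
    try:
        events = run_detector(filtered, detector_name, detector_cfg, n_jobs=n_jobs)
    except Exception as exc:
        raise type(exc)(f"detect stage: {exc}") from exc

    classification = None
    if classify_models is not None:
        try:
            images = np.array([to_model_input(event_tfr(rec, e, tfr_cfg)) for e in events])
            if len(events) == 0:
                images = np.zeros((0, 3, 224, 224))
            classification = run_cascade(list(events), images, classify_models,
                                         inference_cfg)
        except Exception as exc:
            raise type(exc)(f"classify stage: {exc}") from exc

    archive = ResultArchive(
        recording_meta={"source": str(input_path), "fs": rec.fs,
                        "n_channels": rec.n_channels, "n_samples": rec.n_samples,
                        "channel_names": rec.channel_names},
        filter_config=dataclasses.asdict(filter_spec),
        events=events, classification=classification)
    if out_path is not None:
        save_archive(archive, out_path)
    if xlsx_path is not None:
        export_spreadsheet(archive, xlsx_path)
    return archive
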