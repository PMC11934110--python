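"""Core data types for the live-interaction paradigm.

A recording session is built from 30-second condition blocks. Within each
block the stimulus partner watches a short emotionally valenced movie (4 s),
then makes direct or diverted eye contact (5 s), repeats the movie/gaze pair
once, and finally a smart glass turns opaque for a 12-s rest. The four
within-block transitions (movie->gaze, gaze->movie, movie->gaze, gaze->rest)
are the "task-switch times" at which trajectory curvature is later sampled.

Three modalities are recorded simultaneously per subject:

* EEG, 32 channels at 256 Hz (7680 samples per block),
* fNIRS HbDiff (OxyHb - deOxyHb), 134 channels at 8.13 Hz (244 samples),
* facial action units (OpenFace-style continuous intensities), on the fNIRS
  clock (244 samples, 17 AUs by default).

Each subject contributes 24 blocks: 6 per (valence x gaze) condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "Valence",
    "Gaze",
    "ParadigmTimeline",
    "ModalityBlock",
    "SessionRecord",
    "build_timeline",
    "segment_session",
    "write_session",
    "read_session",
    "read_openface_csv",
    "EEG_RATE",
    "FNIRS_RATE",
    "EEG_CHANNELS",
    "FNIRS_CHANNELS",
    "DEFAULT_N_AU",
    "BLOCKS_PER_SESSION",
    "BLOCKS_PER_CONDITION",
]

EEG_RATE = 256.0
#: fNIRS system samples every 123 ms, i.e. 8.13 Hz.
FNIRS_RATE = 8.13
EEG_CHANNELS = 32
FNIRS_CHANNELS = 134
DEFAULT_N_AU = 17
BLOCKS_PER_SESSION = 24
BLOCKS_PER_CONDITION = 6


class Modality(str, Enum):
    EEG = "eeg"
    FNIRS = "fnirs"
    FACEAU = "faceau"


class Valence(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class Gaze(str, Enum):
    DIRECT = "direct"
    DIVERTED = "diverted"


class Group(str, Enum):
    TD = "TD"
    FEP = "FEP"


CONDITIONS: tuple[tuple[Valence, Gaze], ...] = (
    (Valence.POSITIVE, Gaze.DIRECT),
    (Valence.POSITIVE, Gaze.DIVERTED),
    (Valence.NEGATIVE, Gaze.DIRECT),
    (Valence.NEGATIVE, Gaze.DIVERTED),
)


@dataclass(frozen=True)
class ParadigmTimeline:
    """Canonical within-block timeline, in block-local seconds.

    Time convention: t=0 at block onset; sample ``i`` of a modality sampled
    at rate ``r`` covers the half-open interval ``[i/r, (i+1)/r)``.  A switch
    time ``t`` maps to sample index ``floor(t * r)``.
    """

    block_duration: float = 30.0
    #: (label, start, end) of the five within-block segments.
    segments: tuple[tuple[str, float, float], ...] = (
        ("movie", 0.0, 4.0),
        ("gaze", 4.0, 9.0),
        ("movie", 9.0, 13.0),
        ("gaze", 13.0, 18.0),
        ("rest", 18.0, 30.0),
    )

    @property
    def switch_times(self) -> tuple[float, ...]:
        """The four task-switch times (segment boundaries, incl. gaze->rest)."""
        return tuple(end for _, _, end in self.segments[:-1])

    @property
    def movie_segments(self) -> tuple[tuple[float, float], ...]:
        return tuple((a, b) for lab, a, b in self.segments if lab == "movie")

    @property
    def gaze_segments(self) -> tuple[tuple[float, float], ...]:
        return tuple((a, b) for lab, a, b in self.segments if lab == "gaze")

    @property
    def rest_segment(self) -> tuple[float, float]:
        lab, a, b = self.segments[-1]
        assert lab == "rest"
        return (a, b)

    def switch_indices(self, rate: float) -> tuple[int, ...]:
        """Sample indices of the switch times at a given sampling rate."""
        return tuple(int(np.floor(t * rate)) for t in self.switch_times)

    def validate(self) -> None:
        durations = [b - a for _, a, b in self.segments]
        if not np.isclose(sum(durations), self.block_duration):
            raise ValueError("segment durations do not sum to block duration")
        st = self.switch_times
        if len(st) != 4 or any(b <= a for a, b in zip(st, st[1:])):
            raise ValueError("expected 4 strictly increasing switch times")


def build_timeline() -> ParadigmTimeline:
    """Return the canonical 30-s block timeline (switches at 4, 9, 13, 18 s)."""
    tl = ParadigmTimeline()
    tl.validate()
    return tl


def samples_per_block(rate: float, duration: float = 30.0) -> int:
    """Number of samples covering one block: round(rate * duration)."""
    return int(round(rate * duration))


@dataclass
class ModalityBlock:
    """One 30-s recording of one modality: a samples x channels matrix."""

    modality: Modality
    data: np.ndarray
    sampling_rate: float
    valence: Valence
    gaze: Gaze
    subject_id: str
    block_index: int

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.valence = Valence(self.valence)
        self.gaze = Gaze(self.gaze)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("block data must be 2-D (samples x channels)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("block data contains non-finite values")
        expected = samples_per_block(self.sampling_rate)
        if self.data.shape[0] != expected:
            raise ValueError(
                f"{self.modality.value} block has {self.data.shape[0]} samples, "
                f"expected round({self.sampling_rate} * 30) = {expected}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def condition(self) -> tuple[Valence, Gaze]:
        return (self.valence, self.gaze)

    def with_data(self, data: np.ndarray) -> "ModalityBlock":
        """Copy of this block with the data matrix replaced."""
        return ModalityBlock(
            modality=self.modality,
            data=data,
            sampling_rate=self.sampling_rate,
            valence=self.valence,
            gaze=self.gaze,
            subject_id=self.subject_id,
            block_index=self.block_index,
        )


@dataclass
class SessionRecord:
    """A subject's full dataset: 24 blocks per available modality + clinical data.

    ``gaf``, ``panss_pos`` and ``panss_neg`` are raw-scale clinical scores and
    may be NaN (typically for TD controls, who are not scored).
    """

    subject_id: str
    group: Group
    blocks: dict[Modality, list[ModalityBlock]] = field(default_factory=dict)
    gaf: float = float("nan")
    panss_pos: float = float("nan")
    panss_neg: float = float("nan")

    def __post_init__(self) -> None:
        self.group = Group(self.group)

    @property
    def modalities(self) -> list[Modality]:
        return list(self.blocks)

    def validate(self) -> None:
        for mod, blks in self.blocks.items():
            if len(blks) != BLOCKS_PER_SESSION:
                raise ValueError(
                    f"{mod.value}: expected {BLOCKS_PER_SESSION} blocks, got {len(blks)}"
                )
            counts: dict[tuple[Valence, Gaze], int] = {}
            for b in blks:
                counts[b.condition] = counts.get(b.condition, 0) + 1
            if sorted(counts.values()) != [BLOCKS_PER_CONDITION] * 4:
                raise ValueError(f"{mod.value}: conditions do not partition 4 x 6")

    def condition_of_block(self, block_index: int) -> tuple[Valence, Gaze]:
        mod = self.modalities[0]
        return self.blocks[mod][block_index].condition


def segment_session(
    recording: np.ndarray,
    sampling_rate: float,
    schedule: Sequence[tuple[float, str, str]],
    modality: Modality | str,
    subject_id: str = "unknown",
    block_duration: float = 30.0,
) -> list[ModalityBlock]:
    """Cut a continuous recording into 30-s condition blocks.

    Parameters
    ----------
    recording
        Continuous samples x channels matrix.
    schedule
        Sequence of ``(onset_seconds, valence, gaze)`` entries, one per block,
        in any order; blocks must not overlap.
    """
    modality = Modality(modality)
    recording = np.asarray(recording, dtype=np.float64)
    n_per_block = samples_per_block(sampling_rate, block_duration)
    blocks: list[ModalityBlock] = []
    entries = []
    for onset, valence, gaze in schedule:
        try:
            entries.append((float(onset), Valence(valence), Gaze(gaze)))
        except ValueError as exc:
            raise ValueError(f"unknown condition label in schedule: {exc}") from exc
    entries.sort(key=lambda e: e[0])
    prev_end = -np.inf
    for idx, (onset, valence, gaze) in enumerate(entries):
        start = int(np.floor(onset * sampling_rate))
        stop = start + n_per_block
        # tolerate a single-sample overlap: round(rate * 30) can exceed the
        # exact 30-s span (244 samples vs 243.9 at 8.13 Hz)
        if start < prev_end - 1:
            raise ValueError("scheduled blocks overlap")
        prev_end = stop
        if stop > recording.shape[0]:
            raise ValueError(
                f"truncated session: block at t={onset:g}s needs samples up to "
                f"{stop}, recording has {recording.shape[0]}"
            )
        blocks.append(
            ModalityBlock(
                modality=modality,
                data=recording[start:stop],
                sampling_rate=sampling_rate,
                valence=valence,
                gaze=gaze,
                subject_id=subject_id,
                block_index=idx,
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# Session container I/O (HDF5)
# ---------------------------------------------------------------------------
# Layout: groups /eeg /fnirs /faceau, datasets block_000..block_023 each with
# attrs {sampling_rate, valence, gaze}; root attrs {subject_id, group, gaf,
# panss_pos, panss_neg}.


def write_session(record: SessionRecord, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = record.subject_id
        f.attrs["group"] = record.group.value
        f.attrs["gaf"] = float(record.gaf)
        f.attrs["panss_pos"] = float(record.panss_pos)
        f.attrs["panss_neg"] = float(record.panss_neg)
        for mod, blks in record.blocks.items():
            g = f.create_group(mod.value)
            for blk in blks:
                d = g.create_dataset(f"block_{blk.block_index:03d}", data=blk.data)
                d.attrs["sampling_rate"] = float(blk.sampling_rate)
                d.attrs["valence"] = blk.valence.value
                d.attrs["gaze"] = blk.gaze.value


def read_session(path: str | Path) -> SessionRecord:
    path = Path(path)
    with h5py.File(path, "r") as f:
        for attr in ("subject_id", "group"):
            if attr not in f.attrs:
                raise ValueError(f"malformed session container: missing root attribute '{attr}'")
        try:
            group = Group(str(f.attrs["group"]))
        except ValueError as exc:
            raise ValueError(f"malformed session container: bad 'group' value: {exc}") from exc
        record = SessionRecord(
            subject_id=str(f.attrs["subject_id"]),
            group=group,
            gaf=float(f.attrs.get("gaf", np.nan)),
            panss_pos=float(f.attrs.get("panss_pos", np.nan)),
            panss_neg=float(f.attrs.get("panss_neg", np.nan)),
        )
        present = [m for m in Modality if m.value in f]
        missing = [m.value for m in Modality if m.value not in f]
        if missing:
            warnings.warn(
                f"session {record.subject_id}: missing modality group(s) {missing}; "
                "returning partial record",
                stacklevel=2,
            )
        for mod in present:
            g = f[mod.value]
            blks = []
            for name in sorted(g):
                d = g[name]
                for attr in ("sampling_rate", "valence", "gaze"):
                    if attr not in d.attrs:
                        raise ValueError(
                            f"malformed session container: block '{name}' missing attribute '{attr}'"
                        )
                blks.append(
                    ModalityBlock(
                        modality=mod,
                        data=d[()],
                        sampling_rate=float(d.attrs["sampling_rate"]),
                        valence=Valence(str(d.attrs["valence"])),
                        gaze=Gaze(str(d.attrs["gaze"])),
                        subject_id=record.subject_id,
                        block_index=int(name.split("_")[-1]),
                    )
                )
            record.blocks[mod] = blks
    return record


def read_openface_csv(
    path: str | Path,
    au_columns: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Read continuous AU intensities from an OpenFace output CSV.

    OpenFace names continuous-intensity action-unit columns ``AU<nn>_r``.
    Rows where the tracker reported failure (``success`` column equal to 0)
    are replaced by the last valid row (zeros if the first row failed).

    Returns the samples x n_AU matrix and the AU column names used.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    if au_columns is None:
        au_columns = [c for c in df.columns if c.startswith("AU") and c.endswith("_r")]
    else:
        au_columns = list(au_columns)
        absent = [c for c in au_columns if c not in df.columns]
        if absent:
            raise ValueError(f"AU columns not found in CSV: {absent}")
    if not au_columns:
        raise ValueError("no continuous AU intensity columns (AU<nn>_r) found")
    mat = df[au_columns].to_numpy(dtype=np.float64)
    if "success" in df.columns and len(df):
        ok = df["success"].to_numpy() != 0
        if not ok[0]:
            mat[0] = 0.0
            ok[0] = True
        # forward-fill failed-tracking rows with the last valid observation
        last_valid = 0
        for i in range(1, len(ok)):
            if ok[i]:
                last_valid = i
            else:
                mat[i] = mat[last_valid]
    return mat, au_columns
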