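"""Epoch data model, on-disk dataset format, feature cache and report writers.

An :class:`EpochSet` holds fixed-length multi-channel EEG epochs (microvolts)
indexed by ``(subject, session)``.  The on-disk layout is deliberately plain
text so that datasets remain inspectable:

* ``manifest.json`` — montage (ordered channel labels), sampling rate and the
  subject/session file index;
* one tab-separated file per ``(subject, session)`` with columns
  ``epoch_index, channel_label, s0 … s_{L-1}`` — one row per channel per epoch.

Montage order is the canonical channel-to-gene mapping: montage position ``i``
is gene ``i`` (0-based internally; reports always print labels, never indices).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CacheError,
    ChannelCountError,
    DatasetError,
    EmptyFrontError,
    EpochLengthError,
    MissingManifestError,
)

#: Stand-in 56-channel extended 10-20 montage used when no montage is given.
#: The study device also used 56 passive electrodes on the extended 10-20
#: system; the exact enumeration is not published, so this list is an explicit
#: placeholder and every routine in the package is label-agnostic.
DEFAULT_MONTAGE_56: tuple[str, ...] = (
    "FP1", "FPZ", "FP2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO8", "O1", "O2",
)

MANIFEST_NAME = "manifest.json"


@dataclass
class EpochSet:
    """Subject/session-indexed collection of fixed-length multi-channel epochs.

    Parameters
    ----------
    montage:
        Ordered channel labels; position ``i`` maps to gene/channel index ``i``.
    sampling_rate:
        Sampling rate in Hz (> 0).
    epochs:
        Mapping ``(subject, session) -> array (n_epochs, n_channels, n_samples)``
        in microvolts.
    """

    montage: tuple[str, ...]
    sampling_rate: float
    epochs: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.montage = tuple(str(c) for c in self.montage)
        self.epochs = {
            (str(subj), str(sess)): np.asarray(arr, dtype=np.float64)
            for (subj, sess), arr in self.epochs.items()
        }
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise DatasetError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not self.epochs:
            raise DatasetError("EpochSet holds no (subject, session) entries")
        n_samples = None
        for key, arr in self.epochs.items():
            if arr.ndim != 3:
                raise DatasetError(f"{key}: epochs array must be 3-D, got shape {arr.shape}")
            if arr.shape[0] < 1:
                raise DatasetError(f"{key}: every (subject, session) needs >= 1 epoch")
            if arr.shape[1] != len(self.montage):
                raise ChannelCountError(
                    f"{key}: {arr.shape[1]} channel rows but montage has "
                    f"{len(self.montage)} labels"
                )
            if n_samples is None:
                n_samples = arr.shape[2]
            elif arr.shape[2] != n_samples:
                raise EpochLengthError(
                    f"{key}: {arr.shape[2]} samples per epoch, expected {n_samples}"
                )
            if not np.all(np.isfinite(arr)):
                raise DatasetError(f"{key}: non-finite sample values")

    # -- convenience ------------------------------------------------------
    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for subj, _ in self.epochs:
            seen.setdefault(subj, None)
        return list(seen)

    @property
    def sessions(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, sess in self.epochs:
            seen.setdefault(sess, None)
        return list(seen)

    @property
    def n_channels(self) -> int:
        return len(self.montage)

    @property
    def n_samples(self) -> int:
        return next(iter(self.epochs.values())).shape[2]

    def get(self, subject: str, session: str) -> np.ndarray:
        return self.epochs[(str(subject), str(session))]

    def channel_indices(self, labels: Sequence[str]) -> list[int]:
        """Map montage labels to 0-based channel indices."""
        lookup = {lab: i for i, lab in enumerate(self.montage)}
        missing = [lab for lab in labels if lab not in lookup]
        if missing:
            raise DatasetError(f"unknown channel labels: {missing}")
        return [lookup[lab] for lab in labels]

    def equals(self, other: "EpochSet") -> bool:
        return (
            self.montage == other.montage
            and self.sampling_rate == other.sampling_rate
            and set(self.epochs) == set(other.epochs)
            and all(np.array_equal(self.epochs[k], other.epochs[k]) for k in self.epochs)
        )


@dataclass(frozen=True)
class SubjectSplit:
    """Disjoint non-intruder / intruder partition of the subject pool."""

    non_intruders: frozenset[str]
    intruders: frozenset[str]

    def __init__(self, non_intruders: Iterable[str], intruders: Iterable[str]):
        object.__setattr__(self, "non_intruders", frozenset(str(s) for s in non_intruders))
        object.__setattr__(self, "intruders", frozenset(str(s) for s in intruders))
        if not self.non_intruders or not self.intruders:
            raise DatasetError("both split sides must be non-empty")
        if self.non_intruders & self.intruders:
            raise DatasetError(
                f"split sides overlap: {sorted(self.non_intruders & self.intruders)}"
            )

    def validate_against(self, epochset: EpochSet) -> None:
        known = set(epochset.subjects)
        unknown = (self.non_intruders | self.intruders) - known
        if unknown:
            raise DatasetError(f"split references unknown subjects: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# On-disk dataset format
# ---------------------------------------------------------------------------

def _session_filename(subject: str, session: str) -> str:
    return f"epochs_{subject}_{session}.tsv"


def save_epochset(epochset: EpochSet, path: str | Path) -> None:
    """Write ``epochset`` as manifest + one tabular file per (subject, session).

    Floats are serialized at full round-trip precision so that
    ``load_epochset(save_epochset(x)) == x`` bitwise.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    index = []
    for (subj, sess), arr in epochset.epochs.items():
        fname = _session_filename(subj, sess)
        n_epochs, n_channels, n_samples = arr.shape
        rows = arr.reshape(n_epochs * n_channels, n_samples)
        frame = pd.DataFrame(rows, columns=[f"s{i}" for i in range(n_samples)])
        frame.insert(0, "channel_label", list(epochset.montage) * n_epochs)
        frame.insert(0, "epoch_index", np.repeat(np.arange(n_epochs), n_channels))
        # %.17g is the shortest format guaranteed to round-trip float64
        frame.to_csv(root / fname, sep="\t", index=False, float_format="%.17g")
        index.append({"subject": subj, "session": sess, "file": fname,
                      "n_epochs": int(n_epochs)})
    manifest = {
        "montage": list(epochset.montage),
        "sampling_rate": epochset.sampling_rate,
        "sessions": index,
    }
    (root / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))


def load_epochset(path: str | Path) -> EpochSet:
    """Load a dataset directory written by :func:`save_epochset`."""
    root = Path(path)
    manifest_path = root / MANIFEST_NAME
    if not manifest_path.exists():
        raise MissingManifestError(f"no {MANIFEST_NAME} in {root}")
    manifest = json.loads(manifest_path.read_text())
    montage = tuple(manifest["montage"])
    epochs: dict[tuple[str, str], np.ndarray] = {}
    for entry in manifest["sessions"]:
        fpath = root / entry["file"]
        if not fpath.exists():
            raise DatasetError(f"manifest references missing file {fpath}")
        frame = pd.read_csv(fpath, sep="\t", float_precision="round_trip")
        sample_cols = [c for c in frame.columns if c.startswith("s") and c[1:].isdigit()]
        sample_cols.sort(key=lambda c: int(c[1:]))
        n_epochs = int(frame["epoch_index"].nunique())
        if len(frame) != n_epochs * len(montage):
            raise ChannelCountError(
                f"{fpath}: {len(frame)} rows for {n_epochs} epochs, expected "
                f"{n_epochs * len(montage)} ({len(montage)}-channel montage)"
            )
        expected_epochs = entry.get("n_epochs")
        if expected_epochs is not None and n_epochs != expected_epochs:
            raise EpochLengthError(
                f"{fpath}: {n_epochs} epochs found, manifest says {expected_epochs}"
            )
        frame = frame.sort_values(["epoch_index"], kind="stable")
        for epoch_idx, group in frame.groupby("epoch_index", sort=True):
            if list(group["channel_label"]) != list(montage):
                raise ChannelCountError(
                    f"{fpath}: epoch {epoch_idx} channel labels do not match montage"
                )
        arr = frame[sample_cols].to_numpy(dtype=np.float64)
        epochs[(entry["subject"], entry["session"])] = arr.reshape(
            n_epochs, len(montage), len(sample_cols)
        )
    return EpochSet(montage=montage, sampling_rate=float(manifest["sampling_rate"]),
                    epochs=epochs)


# ---------------------------------------------------------------------------
# Feature cache
# ---------------------------------------------------------------------------

N_FEATURES_PER_CHANNEL = 8


@dataclass
class FeatureCache:
    """Precomputed 8-feature block per channel per epoch.

    The cache is computed once over *all* channels so that any channel mask can
    be served by slicing, never by recomputation.  ``blocks`` maps
    ``(subject, session)`` to an array of shape ``(n_epochs, n_channels, 8)``.
    ``provenance`` records feature order and extraction settings.
    """

    montage: tuple[str, ...]
    blocks: dict[tuple[str, str], np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.montage = tuple(self.montage)
        for key, arr in self.blocks.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim != 3 or arr.shape[1] != len(self.montage) or \
                    arr.shape[2] != N_FEATURES_PER_CHANNEL:
                raise CacheError(
                    f"{key}: cache block shape {arr.shape} incompatible with "
                    f"{len(self.montage)}-channel montage and 8 features"
                )
            if not np.all(np.isfinite(arr)):
                raise CacheError(f"{key}: non-finite feature values")
            self.blocks[key] = arr

    def block(self, subject: str, session: str, epoch: int, channel: int) -> np.ndarray:
        return self.blocks[(str(subject), str(session))][epoch, channel]

    def instance_matrix(self, subject: str, session: str,
                        mask: Sequence[int]) -> np.ndarray:
        """Feature vectors for every epoch of (subject, session), masked.

        Blocks of the masked channels are concatenated in montage order,
        giving one row of length ``8 * len(mask)`` per epoch.
        """
        idx = sorted(int(i) for i in mask)
        if not idx:
            raise ValueError("empty channel mask")
        arr = self.blocks[(str(subject), str(session))]
        return arr[:, idx, :].reshape(arr.shape[0], len(idx) * N_FEATURES_PER_CHANNEL)

    def is_complete_for(self, epochset: EpochSet) -> bool:
        for key, arr in epochset.epochs.items():
            blk = self.blocks.get(key)
            if blk is None or blk.shape[0] != arr.shape[0]:
                return False
        return True

    # -- serialization ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        rows = []
        for (subj, sess), arr in self.blocks.items():
            n_epochs, n_channels, _ = arr.shape
            flat = arr.reshape(n_epochs * n_channels, N_FEATURES_PER_CHANNEL)
            frame = pd.DataFrame(flat, columns=[f"f{i}" for i in range(N_FEATURES_PER_CHANNEL)])
            frame.insert(0, "channel_label", list(self.montage) * n_epochs)
            frame.insert(0, "epoch_index", np.repeat(np.arange(n_epochs), n_channels))
            frame.insert(0, "session", sess)
            frame.insert(0, "subject", subj)
            rows.append(frame)
        table = pd.concat(rows, ignore_index=True)
        header = "# provenance: " + json.dumps(
            {"montage": list(self.montage), **self.provenance}
        )
        with open(path, "w") as fh:
            fh.write(header + "\n")
            table.to_csv(fh, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def load(cls, path: str | Path) -> "FeatureCache":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# provenance: "):
                raise CacheError(f"{path}: missing provenance header")
            meta = json.loads(header[len("# provenance: "):])
            table = pd.read_csv(fh, sep="\t", dtype={"subject": str, "session": str},
                                float_precision="round_trip")
        montage = tuple(meta.pop("montage"))
        fcols = [f"f{i}" for i in range(N_FEATURES_PER_CHANNEL)]
        blocks: dict[tuple[str, str], np.ndarray] = {}
        for (subj, sess), group in table.groupby(["subject", "session"], sort=False):
            group = group.sort_values("epoch_index", kind="stable")
            n_epochs = int(group["epoch_index"].nunique())
            arr = group[fcols].to_numpy(dtype=np.float64)
            blocks[(str(subj), str(sess))] = arr.reshape(
                n_epochs, len(montage), N_FEATURES_PER_CHANNEL
            )
        return cls(montage=montage, blocks=blocks, provenance=meta)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

PARETO_REPORT_COLUMNS = ["n_channels", "accuracy", "TAR", "TRR", "nu", "gamma", "channels"]


def write_pareto_report(front, path: str | Path, montage: Sequence[str]) -> None:
    """Write one row per Pareto-front member, sorted by channel count.

    ``front`` is any object with a ``members`` list whose items expose
    ``objectives`` (``n_channels``, ``accuracy``, ``tar``, ``trr``), ``nu``,
    ``gamma`` and ``channel_indices``.  Channels are printed as montage labels.
    """
    members = list(getattr(front, "members", front))
    if not members:
        raise EmptyFrontError("cannot report an empty front")
    montage = list(montage)
    rows = []
    for m in members:
        labels = " ".join(montage[i] for i in sorted(m.channel_indices))
        rows.append({
            "n_channels": m.objectives.n_channels,
            "accuracy": m.objectives.accuracy,
            "TAR": m.objectives.tar,
            "TRR": m.objectives.trr,
            "nu": m.nu,
            "gamma": m.gamma,
            "channels": labels,
        })
    frame = pd.DataFrame(rows, columns=PARETO_REPORT_COLUMNS)
    frame = frame.sort_values("n_channels", kind="stable")
    frame.to_csv(path, sep="\t", index=False)


def read_pareto_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def channel_overlap_summary(subsets: Sequence[set[str] | frozenset[str]]) -> pd.DataFrame:
    """Membership counts of channel labels across several selected subsets.

    A textual stand-in for a Venn diagram: each label appearing in at least one
    subset is listed with the number of subsets containing it, sorted by count
    descending then label.
    """
    subsets = [set(s) for s in subsets]
    if len(subsets) < 2:
        raise ValueError("need at least 2 subsets to compare")
    counts: dict[str, int] = {}
    for sub in subsets:
        for label in sub:
            counts[label] = counts.get(label, 0) + 1
    frame = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["label", "count"],
    )
    return frame
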