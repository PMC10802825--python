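"""Domain containers, validation and CSV I/O for VT episodes.

An :class:`Episode` is one device-detected ventricular tachycardia event:
an ordered series of cycle lengths (CLs) in milliseconds together with the
outcome label.  By convention element 0 of ``cl_ms`` is CL1, the interval
between the initiating premature ventricular contraction (PVC) and the
first VT beat; subsequent elements are the device-measured VT cycle
lengths.  Episodes are analysis-eligible when they last longer than 10
CLs, i.e. contain at least 11.

Cohorts travel as long-format CSV with columns
``episode_id,patient_id,label,beat_index,cl_ms`` (0-based contiguous
``beat_index`` per episode).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABELS = ("terminating", "sustained", "unknown")

#: analysis eligibility: an episode must last longer than 10 CLs
MIN_ANALYSIS_BEATS = 11

#: physiological plausibility band for VT cycle lengths (ms); values
#: outside it trigger a validation warning, not an error
PLAUSIBLE_CL_MS = (100.0, 1000.0)

CSV_COLUMNS = ["episode_id", "patient_id", "label", "beat_index", "cl_ms"]


class CohortFormatError(ValueError):
    """The CSV does not conform to the long cohort format."""


class EpisodeValidationError(ValueError):
    """An episode violates a structural invariant."""


@dataclass
class Episode:
    """One VT episode as logged by an ICD.

    Parameters
    ----------
    episode_id, patient_id
        Identifiers; ``episode_id`` is unique within a cohort.
    label
        ``"terminating"`` (self-terminated without therapy),
        ``"sustained"`` (required ATP or shock) or ``"unknown"``.
    cl_ms
        Ordered cycle lengths in milliseconds; element 0 is the
        PVC-coupled CL1.
    zone_rate_bpm, detection_time_s
        Optional device-programming metadata, carried but never analysed.
    """

    episode_id: str
    patient_id: str
    label: str
    cl_ms: np.ndarray
    zone_rate_bpm: float | None = None
    detection_time_s: float | None = None

    def __post_init__(self) -> None:
        self.cl_ms = np.asarray(self.cl_ms, dtype=float)

    @property
    def n_beats(self) -> int:
        return len(self.cl_ms)

    def validate(self, require_length: bool = True) -> None:
        """Raise :class:`EpisodeValidationError` on invariant violations.

        Out-of-band but positive CLs (outside 100-1000 ms) only warn.
        With ``require_length=False`` the >10-CL eligibility check is
        skipped (used when loading for inspection rather than analysis).
        """
        if self.label not in LABELS:
            raise EpisodeValidationError(
                f"episode {self.episode_id!r}: label {self.label!r} not in {LABELS}"
            )
        if self.cl_ms.ndim != 1 or self.n_beats == 0:
            raise EpisodeValidationError(
                f"episode {self.episode_id!r}: cl_ms must be a non-empty 1-D series"
            )
        if not np.all(np.isfinite(self.cl_ms)) or np.any(self.cl_ms <= 0):
            raise EpisodeValidationError(
                f"episode {self.episode_id!r}: all cycle lengths must be finite and > 0"
            )
        if require_length and self.n_beats < MIN_ANALYSIS_BEATS:
            raise EpisodeValidationError(
                f"episode {self.episode_id!r}: {self.n_beats} CLs; analysis requires "
                f">= {MIN_ANALYSIS_BEATS} (episodes lasting longer than 10 CLs)"
            )
        lo, hi = PLAUSIBLE_CL_MS
        if np.any((self.cl_ms < lo) | (self.cl_ms > hi)):
            warnings.warn(
                f"episode {self.episode_id!r}: cycle lengths outside the "
                f"physiologically plausible band [{lo:g}, {hi:g}] ms",
                stacklevel=2,
            )
        for name in ("zone_rate_bpm", "detection_time_s"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise EpisodeValidationError(
                    f"episode {self.episode_id!r}: {name} must be positive if given"
                )


@dataclass
class Cohort:
    """A set of episodes plus free-text provenance (file path or seed/config)."""

    episodes: list[Episode] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.episodes)

    def __iter__(self):
        return iter(self.episodes)

    def labels(self) -> list[str]:
        return [e.label for e in self.episodes]

    def validate(self, require_length: bool = True) -> None:
        ids = [e.episode_id for e in self.episodes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise EpisodeValidationError(f"duplicate episode_id(s): {dupes}")
        for e in self.episodes:
            e.validate(require_length=require_length)


def episode_duration_s(e: Episode) -> float:
    """Total episode duration in seconds: ``sum(cl_ms) / 1000``."""
    if e.n_beats == 0:
        raise EpisodeValidationError("cannot compute duration of an empty episode")
    return float(np.sum(e.cl_ms)) / 1000.0


def read_cohort(path, strict: bool = True) -> Cohort:
    """Read a long-format cohort CSV.

    Each distinct ``episode_id`` becomes one :class:`Episode` with its
    ``cl_ms`` ordered by ``beat_index`` (which must be contiguous from 0
    regardless of row order).  With ``strict=True`` any invariant
    violation raises; with ``strict=False`` invalid episodes are dropped
    with a logged reason.
    """
    df = pd.read_csv(
        path,
        dtype={"episode_id": str, "patient_id": str, "label": str},
        float_precision="round_trip",
    )
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing column(s) {missing}")

    episodes: list[Episode] = []
    for eid, grp in df.groupby("episode_id", sort=True):
        grp = grp.sort_values("beat_index")
        idx = grp["beat_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise CohortFormatError(
                f"{path}: episode {eid!r} has non-contiguous beat_index "
                f"(expected 0..{len(idx) - 1})"
            )
        pid = grp["patient_id"].iloc[0]
        label = grp["label"].iloc[0]
        ep = Episode(
            episode_id=str(eid),
            patient_id=str(pid),
            label=str(label),
            cl_ms=grp["cl_ms"].to_numpy(dtype=float),
        )
        try:
            ep.validate()
        except EpisodeValidationError as err:
            if strict:
                raise
            logger.warning("dropping episode %r: %s", eid, err)
            continue
        episodes.append(ep)

    cohort = Cohort(episodes=episodes, provenance=str(path))
    cohort.validate(require_length=False)
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write the long-format cohort CSV.

    CL values are serialized with full ``repr`` precision so that
    ``read_cohort(write_cohort(c))`` round-trips ids, labels and CL
    values bit-exactly.
    """
    rows = []
    for e in cohort.episodes:
        for i, cl in enumerate(e.cl_ms):
            # repr round-trips IEEE doubles exactly (shortest exact decimal)
            rows.append((e.episode_id, e.patient_id, e.label, i, repr(float(cl))))
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def metadata_sidecar(cohort: Cohort) -> dict:
    """Optional JSON sidecar payload keyed by episode_id."""
    out = {}
    for e in cohort.episodes:
        if e.zone_rate_bpm is not None or e.detection_time_s is not None:
            out[e.episode_id] = {
                "zone_rate_bpm": e.zone_rate_bpm,
                "detection_time_s": e.detection_time_s,
            }
    return out
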