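"""Session configuration and the published ten-subject profile bundle.

A session config is a YAML mapping validated strictly (unknown keys are
rejected, every module invariant is checked at load time).  The ten subjects'
audiograms and comfort targets — standard and personalized — ship as package
data for regression tests and as ready-made listener profiles.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .engine import (
    DEFAULT_AT_DB,
    DEFAULT_BURN_IN_S,
    DEFAULT_LDL_OFFSET_DB,
    DEFAULT_MAX_GAIN_DB,
    DEFAULT_SLEW_DB_PER_S,
    ListenerProfile,
    MapParameters,
)
from .filterbank import ADRO_BAND_EDGES_HZ, TRAINING_BAND_EDGES_HZ
from .levels import DEFAULT_PERCENTILES, DEFAULT_STEP_DB
from .mlirl import DEFAULT_SCALES


class ConfigError(ValueError):
    pass


# Published ten-subject measurements: per subject the ten-band audiogram
# (dB HL), the measured standard comfort targets (dB SPL), and the comfort
# targets after online personalization (dB SPL), used as reference vectors.
TABLE1_SUBJECTS = (
    {
        "subject": 1,
        "audiogram": (20, 20, 15, 15, 15, 15, 15, 15, 25, 40),
        "standard_ct": (70, 70, 70, 70, 72, 75, 77, 80, 75, 70),
        "personalized_ct": (35, 35, 35, 35, 55, 75, 57, 40, 37, 35),
    },
    {
        "subject": 2,
        "audiogram": (5, 10, 10, 15, 15, 15, 15, 20, 20, 30),
        "standard_ct": (70, 70, 75, 80, 80, 80, 80, 80, 77, 75),
        "personalized_ct": (35, 35, 37, 40, 60, 80, 80, 80, 77, 75),
    },
    {
        "subject": 3,
        "audiogram": (20, 25, 15, 25, 25, 25, 20, 20, 30, 35),
        "standard_ct": (75, 75, 75, 75, 72, 70, 75, 80, 72, 65),
        "personalized_ct": (75, 75, 75, 75, 55, 35, 57, 80, 72, 65),
    },
    {
        "subject": 4,
        "audiogram": (45, 40, 40, 40, 40, 45, 40, 35, 45, 50),
        "standard_ct": (78, 78, 80, 82, 81, 80, 80, 80, 77, 75),
        "personalized_ct": (39, 39, 40, 41, 40, 40, 60, 80, 58, 37),
    },
    {
        "subject": 5,
        "audiogram": (40, 45, 50, 65, 65, 55, 45, 50, 60, 60),
        "standard_ct": (76, 76, 79, 82, 76, 70, 71, 72, 73, 75),
        "personalized_ct": (38, 38, 60, 82, 58, 35, 53, 72, 54, 37),
    },
    {
        "subject": 6,
        "audiogram": (20, 20, 20, 20, 25, 25, 30, 40, 50, 45),
        "standard_ct": (78, 78, 80, 82, 79, 77, 78, 80, 80, 80),
        "personalized_ct": (39, 39, 59, 80, 59, 38, 59, 80, 80, 80),
    },
    {
        "subject": 7,
        "audiogram": (15, 15, 25, 25, 30, 30, 30, 25, 40, 45),
        "standard_ct": (76, 76, 79, 82, 82, 82, 79, 77, 71, 65),
        "personalized_ct": (38, 38, 39, 41, 41, 41, 59, 77, 71, 65),
    },
    {
        "subject": 8,
        "audiogram": (40, 30, 20, 20, 10, 10, 20, 50, 55, 40),
        "standard_ct": (82, 82, 77, 72, 71, 70, 72, 75, 70, 65),
        "personalized_ct": (41, 41, 38, 36, 35, 35, 36, 37, 34, 32),
    },
    {
        "subject": 9,
        "audiogram": (15, 15, 10, 20, 20, 20, 20, 35, 50, 40),
        "standard_ct": (80, 80, 81, 82, 78, 75, 80, 85, 82, 80),
        "personalized_ct": (40, 40, 40, 41, 39, 37, 39, 42, 61, 80),
    },
    {
        "subject": 10,
        "audiogram": (10, 15, 10, 35, 45, 45, 30, 25, 15, 20),
        "standard_ct": (56, 56, 61, 67, 67, 67, 66, 65, 57, 50),
        "personalized_ct": (28, 28, 30, 33, 33, 33, 32, 32, 41, 50),
    },
)


def load_table1_profiles(
    at_db: float = DEFAULT_AT_DB,
    ldl_offset_db: float = DEFAULT_LDL_OFFSET_DB,
    mg_db: float = DEFAULT_MAX_GAIN_DB,
) -> list[ListenerProfile]:
    """The ten published subjects as ready-made listener profiles.

    AT, LDL, MPO and MG are not published, so they come from the package
    defaults (AT flat 20 dB SPL, LDL = CT + 25, MPO = LDL, MG = 30 dB).
    Raises :class:`ConfigError` if the packaged data are malformed.
    """
    if len(TABLE1_SUBJECTS) != 10:
        raise ConfigError("packaged subject table must hold exactly 10 subjects")
    profiles = []
    for row in TABLE1_SUBJECTS:
        for key in ("audiogram", "standard_ct", "personalized_ct"):
            if len(row[key]) != 10:
                raise ConfigError(
                    f"subject {row['subject']}: {key} must have 10 bands"
                )
        profiles.append(
            ListenerProfile(
                audiogram_db_hl=np.asarray(row["audiogram"], dtype=np.float64),
                map=MapParameters.from_standard_ct(
                    row["standard_ct"], at_db=at_db, ldl_offset_db=ldl_offset_db, mg_db=mg_db
                ),
                reference_personalized_ct=np.asarray(
                    row["personalized_ct"], dtype=np.float64
                ),
                subject=row["subject"],
            )
        )
    return profiles


@dataclass(frozen=True)
class SessionConfig:
    """Validated parameters for a full fitting + personalization session."""

    adro_band_edges_hz: tuple = ADRO_BAND_EDGES_HZ
    training_band_edges_hz: tuple = TRAINING_BAND_EDGES_HZ
    spl_at_full_scale: float = 100.0
    percentiles: tuple = DEFAULT_PERCENTILES
    percentile_step_db: float = DEFAULT_STEP_DB
    slew_rate_db_per_s: float = DEFAULT_SLEW_DB_PER_S
    burn_in_s: float = DEFAULT_BURN_IN_S
    at_db: float = DEFAULT_AT_DB
    ldl_offset_db: float = DEFAULT_LDL_OFFSET_DB
    max_gain_db: float = DEFAULT_MAX_GAIN_DB
    scales: tuple = DEFAULT_SCALES
    n_trajectories: int = 7
    n_pairs_per_trajectory: int = 31
    n_test_pairs: int = 30
    snr_db: float = 5.0
    utterance_duration_s: float = 2.5
    n_babble_talkers: int = 8
    seed: int = 0
    standard_ct: tuple | None = None
    audiogram: tuple | None = None

    def __post_init__(self) -> None:
        for name in ("adro_band_edges_hz", "training_band_edges_hz", "percentiles", "scales"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        if self.standard_ct is not None:
            object.__setattr__(self, "standard_ct", tuple(self.standard_ct))
        if self.audiogram is not None:
            object.__setattr__(self, "audiogram", tuple(self.audiogram))
        self._validate()

    def _validate(self) -> None:
        edges = self.adro_band_edges_hz
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigError("adro_band_edges_hz: edges must be strictly increasing")
        if not (self.percentiles[0] > self.percentiles[1] > self.percentiles[2]):
            raise ConfigError("percentiles: must be ordered high > mid > low")
        for name in (
            "percentile_step_db",
            "slew_rate_db_per_s",
            "spl_at_full_scale",
            "utterance_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be positive")
        for name in ("n_trajectories", "n_pairs_per_trajectory", "n_test_pairs"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name}: must be at least 1")
        if 1.0 not in self.scales:
            raise ConfigError("scales: must include 1.0 (the standard profile)")
        if self.standard_ct is not None:
            ct = np.asarray(self.standard_ct, dtype=np.float64)
            if np.any(self.at_db >= ct):
                raise ConfigError("standard_ct: AT must be below CT in every band")
        if self.ldl_offset_db <= 0:
            raise ConfigError("ldl_offset_db: must be positive")

    def listener_profile(self) -> ListenerProfile:
        if self.standard_ct is None:
            raise ConfigError("config carries no standard_ct")
        audiogram = (
            self.audiogram if self.audiogram is not None else tuple([0.0] * len(self.standard_ct))
        )
        return ListenerProfile(
            audiogram_db_hl=np.asarray(audiogram, dtype=np.float64),
            map=MapParameters.from_standard_ct(
                self.standard_ct,
                at_db=self.at_db,
                ldl_offset_db=self.ldl_offset_db,
                mg_db=self.max_gain_db,
            ),
        )


def load_config(path) -> SessionConfig:
    """Load and strictly validate a YAML session config.

    Unknown keys raise a :class:`ConfigError` naming the key; all defaults
    (percentile triplet, 3 dB/s slew, scale set, protocol sizes, 5 dB SNR,
    2.5 s utterances) fill in when omitted.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    known = set(SessionConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown config key: {key!r}")
    try:
        return SessionConfig(**raw)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def save_config(cfg: SessionConfig, path) -> None:
    data = {k: v for k, v in asdict(cfg).items() if v is not None}
    data = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
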