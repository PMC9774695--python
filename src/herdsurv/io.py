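"""Data containers, file formats, configuration and logging.

Everything on disk is plain CSV/JSON/YAML:

* ``sensor.csv`` — one row per cow-day: ``cow_id, date, dim, my_kg, bw_kg,
  rum_min``.  Dates are ISO-8601; ``dim`` (days in milk) is integer with the
  calving day at DIM 0.  A missing daily value is an empty field.
* ``cows.csv`` — one row per cow: ``cow_id, birth_date, calving1_date,
  culling_date, afc_days``; an empty ``culling_date`` means the cow was still
  on the farm at the end of the dataset (right-censored).
* Pipeline configuration is YAML, mapped onto :class:`PipelineConfig`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("herdsurv")
if not logger.handlers:  # default: stderr, overridable by the CLI
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

#: wide-format sensor columns and the outcome labels used throughout
OUTCOME_COLS = ("my_kg", "bw_kg", "rum_min")
OUTCOME_KINDS = ("MY", "BW", "RUM")

SENSOR_COLUMNS = ["cow_id", "date", "dim", "my_kg", "bw_kg", "rum_min"]
COW_COLUMNS = ["cow_id", "birth_date", "calving1_date", "culling_date", "afc_days"]


@dataclass(frozen=True)
class SurvivalRecord:
    """Days from first calving to culling (event=1) or censoring (event=0)."""

    T: int
    event: int

    def __post_init__(self):
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if self.T < 1:
            raise ValueError("survival time must be >= 1 day")


@dataclass
class HerdDataset:
    """One herd: per-cow daily sensor series plus the calving/culling table.

    ``survival`` (cow_id, T, event) and ``afc_cat`` columns are attached by
    the preprocessing stage; raw datasets carry only ``sensor`` and ``cows``.
    """

    sensor: pd.DataFrame
    cows: pd.DataFrame
    end_date: pd.Timestamp
    t1: int | None = None
    t2: int | None = None
    survival: pd.DataFrame | None = None

    def copy(self) -> "HerdDataset":
        return HerdDataset(
            sensor=self.sensor.copy(),
            cows=self.cows.copy(),
            end_date=self.end_date,
            t1=self.t1,
            t2=self.t2,
            survival=None if self.survival is None else self.survival.copy(),
        )

    @property
    def n_cows(self) -> int:
        return len(self.cows)


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

def read_sensor_csv(path) -> pd.DataFrame:
    """Read and validate a sensor file.

    Raises ``ValueError`` on a missing column, an unparseable date, a
    negative sensor value, a rumination value above 1440 min/day, or a
    duplicated (cow, day) record.
    """
    df = pd.read_csv(path)
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sensor file {path} missing columns: {missing}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable ISO-8601 date in {path}: {exc}") from exc
    df["dim"] = df["dim"].astype(int)
    for col in OUTCOME_COLS:
        df[col] = pd.to_numeric(df[col])
        if (df[col] < 0).any():
            bad = df.loc[df[col] < 0].iloc[0]
            raise ValueError(f"negative {col} for cow {bad['cow_id']} at DIM {bad['dim']}")
    if (df["rum_min"] > 1440).any():
        bad = df.loc[df["rum_min"] > 1440].iloc[0]
        raise ValueError(
            f"rumination above 1440 min/day for cow {bad['cow_id']} at DIM {bad['dim']}"
        )
    dup = df.duplicated(subset=["cow_id", "dim"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise ValueError(f"duplicate record for cow {bad['cow_id']} at DIM {bad['dim']}")
    return df[SENSOR_COLUMNS]


def read_cows_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cows file {path} missing columns: {missing}")
    for col in ("birth_date", "calving1_date", "culling_date"):
        df[col] = pd.to_datetime(df[col], format="ISO8601", errors="raise")
    if df["cow_id"].duplicated().any():
        raise ValueError("duplicate cow_id in cows file")
    df["afc_days"] = df["afc_days"].astype(int)
    return df[COW_COLUMNS]


def read_herd(directory, end_date=None, t1=None, t2=None) -> HerdDataset:
    """Load ``sensor.csv`` + ``cows.csv`` from a directory."""
    directory = Path(directory)
    sensor = read_sensor_csv(directory / "sensor.csv")
    cows = read_cows_csv(directory / "cows.csv")
    if end_date is None:
        meta = directory / "herd.json"
        if meta.exists():
            import json

            m = json.loads(meta.read_text())
            end_date = pd.Timestamp(m["end_date"])
            t1 = t1 if t1 is not None else m.get("t1")
            t2 = t2 if t2 is not None else m.get("t2")
        else:
            end_date = sensor["date"].max()
    return HerdDataset(sensor=sensor, cows=cows, end_date=pd.Timestamp(end_date), t1=t1, t2=t2)


def write_herd(dataset: HerdDataset, directory) -> None:
    """Write ``sensor.csv``, ``cows.csv`` and ``herd.json`` (end date, horizons)."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sensor = dataset.sensor.copy()
    sensor["date"] = sensor["date"].dt.strftime("%Y-%m-%d")
    sensor.to_csv(directory / "sensor.csv", index=False, float_format="%.3f")
    cows = dataset.cows.copy()
    for col in ("birth_date", "calving1_date", "culling_date"):
        cows[col] = pd.to_datetime(cows[col]).dt.strftime("%Y-%m-%d")
    cows["culling_date"] = cows["culling_date"].fillna("")
    cows.to_csv(directory / "cows.csv", index=False)
    meta = {
        "end_date": str(pd.Timestamp(dataset.end_date).date()),
        "t1": dataset.t1,
        "t2": dataset.t2,
    }
    (directory / "herd.json").write_text(json.dumps(meta, indent=1))


# ----------------------------------------------------------------------
# pipeline configuration
# ----------------------------------------------------------------------

@dataclass
class MCMCConfig:
    """Sampler sizes and tuning; see docs/methods.md for the rationale."""

    chains: int = 2
    burn: int = 1500
    keep: int = 1500
    thin: int = 1
    target_accept: float = 0.3
    baseline_intervals: int = 6

    def to_dict(self):
        return dataclasses.asdict(self)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    sensor_path: str | None = None
    cows_path: str | None = None
    out_dir: str = "herdsurv_out"
    # model
    association: str = "slope"          # "slope" (default) or "value"
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    obs_thin: int = 1                   # keep every k-th observation day
    # scenarios
    v_list: tuple[int, ...] = (60, 150, 240)
    t1: int | None = None               # horizons; None -> estimate from data
    t2: int | None = None
    # evaluation
    folds: int = 3
    repeats: int = 3
    threshold: float = 0.5
    n_draws: int = 500
    min_test_dim: int = 240             # test cows must have survived this long
    # seeds (all explicit)
    partition_seed: int = 1
    mcmc_seed: int = 2
    sim_seed: int = 3

    def __post_init__(self):
        if isinstance(self.mcmc, dict):
            self.mcmc = MCMCConfig(**self.mcmc)
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("classification threshold must be in (0, 1)")
        if any(not 5 <= v <= 305 for v in self.v_list):
            raise ValueError("observation windows v must lie in [5, 305] DIM")
        if self.association not in ("slope", "value"):
            raise ValueError("association must be 'slope' or 'value'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "v_list" in raw:
            raw["v_list"] = tuple(raw["v_list"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["v_list"] = list(self.v_list)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
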