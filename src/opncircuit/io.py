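"""CSV input/output with deterministic formatting.

External tables use assay units (ng/mL); loaders convert concentrations to
the model's internal nM using the default molecular masses.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import units
from .kinetics import DigestionTimeCourse

# %.17g round-trips IEEE doubles exactly, so cached stage outputs reload
# to bit-identical values on resume
FLOAT_FORMAT = "%.17g"


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    return path


def sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_cohort(path, opn_kda: float = units.OPN_KDA,
                prot_kda: float = units.PROTEASOME_KDA) -> pd.DataFrame:
    """Cohort CSV (opn_ng_ml, proteasome_ng_ml) -> internal nM columns."""
    df = pd.read_csv(path, float_precision="round_trip")
    df["opn_nm"] = units.ng_ml_to_nm(df["opn_ng_ml"], opn_kda)
    df["prot_nm"] = units.ng_ml_to_nm(df["proteasome_ng_ml"], prot_kda)
    if (df["opn_nm"] <= 0).any() or (df["prot_nm"] <= 0).any():
        raise ValueError("cohort concentrations must be positive")
    return df


def load_digestion(path) -> list[DigestionTimeCourse]:
    """Digestion CSV -> one DigestionTimeCourse per (substrate, isoform)."""
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for (s, iso), grp in df.groupby(["substrate", "isoform"], sort=True):
        wide = grp.pivot_table(index="replicate", columns="time_h",
                               values="relative_remaining")
        times = wide.columns.to_numpy(dtype=float)
        out.append(DigestionTimeCourse(
            substrate=s, isoform=iso,
            p_conc=float(grp["proteasome_nM"].iloc[0]),
            opn0=float(grp["opn0_nM"].iloc[0]),
            times=times,
            observations=wide.to_numpy(dtype=float)))
    return out


def load_migration(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if (df["percent_of_control"] < 0).any():
        raise ValueError("migration readouts must be >= 0")
    return df


def trajectory_frame(t, states, species_names, sample_id=0) -> pd.DataFrame:
    rows = []
    for j, name in enumerate(species_names):
        rows.append(pd.DataFrame({"time_h": np.asarray(t), "species": name,
                                  "value": states[:, j],
                                  "sample_id": sample_id}))
    return pd.concat(rows, ignore_index=True)
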