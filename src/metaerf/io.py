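"""Delimited-file readers and writers for study bundles and artifacts.

All tables are UTF-8 CSV with deterministic column order; dates ISO-8601;
every artifact carries a header comment recording the configuration hash and
master seed, so a run can be audited from its outputs alone.  Synthetic and
real studies share the same on-disk layout and are interchangeable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

EARTH_KM_PER_DEG = 111.32


@dataclass
class Study:
    """A loaded study bundle (same interface as a synthetic study)."""

    locations: pd.DataFrame
    metavars: pd.DataFrame
    series: pd.DataFrame
    demography: pd.DataFrame
    age_groups: dict

    @property
    def age_group_bounds(self):
        return self.age_groups


def config_hash(config) -> str:
    """Stable short hash of a configuration mapping."""
    if hasattr(config, "__dict__"):
        config = {k: v for k, v in vars(config).items()}
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta=None):
    """Write a CSV with a header comment carrying run metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if meta:
            pairs = " ".join(f"{k}={v}" for k, v in meta.items())
            fh.write(f"# {pairs}\n")
        df.to_csv(fh, index=False)


def read_table(path, **kw):
    return pd.read_csv(path, comment="#", **kw)


def project_planar(locations):
    """Local equirectangular projection of lon/lat to planar km about the
    study centroid (adds x_km / y_km columns)."""
    df = locations.copy()
    lat0 = df["lat"].mean()
    lon0 = df["lon"].mean()
    df["x_km"] = (df["lon"] - lon0) * EARTH_KM_PER_DEG * np.cos(np.deg2rad(lat0))
    df["y_km"] = (df["lat"] - lat0) * EARTH_KM_PER_DEG
    return df


def _require(df, cols, fname):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{fname}: missing columns {missing}")


def load_dataset(path) -> Study:
    """Load and validate a study bundle directory.

    Expected files: locations.csv, metavars.csv, series.csv, demography.csv,
    age_groups.csv.  Raises ValueError with file context on missing columns,
    duplicated (location, age_group, date) rows or non-monotone dates.
    """
    path = Path(path)
    loc = read_table(path / "locations.csv")
    _require(loc, ["location", "lon", "lat", "region", "observed"],
             "locations.csv")
    if not {"x_km", "y_km"} <= set(loc.columns):
        loc = project_planar(loc)

    metavars = read_table(path / "metavars.csv").set_index("location")

    series = read_table(path / "series.csv", parse_dates=["date"])
    _require(series, ["location", "age_group", "date", "temp", "deaths"],
             "series.csv")
    dup = series.duplicated(["location", "age_group", "date"])
    if dup.any():
        bad = series.loc[dup, "location"].iloc[0]
        raise ValueError(f"series.csv: duplicated (location, date) rows for "
                         f"{bad!r}")
    for (l, a), g in series.groupby(["location", "age_group"]):
        if not g["date"].is_monotonic_increasing:
            raise ValueError(f"series.csv: non-monotone dates for {l!r}/{a!r}")

    demo = read_table(path / "demography.csv")
    _require(demo, ["location", "age_group", "age", "deaths", "population",
                    "life_expectancy"], "demography.csv")

    ag = read_table(path / "age_groups.csv")
    _require(ag, ["age_group", "lower", "upper"], "age_groups.csv")
    groups = {r["age_group"]: (int(r["lower"]),
                               None if pd.isna(r["upper"]) else int(r["upper"]))
              for _, r in ag.iterrows()}
    return Study(locations=loc, metavars=metavars, series=series,
                 demography=demo, age_groups=groups)


def write_dataset(study, path, meta=None):
    """Write a study bundle (synthetic or loaded) to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_table(study.locations, path / "locations.csv", meta)
    write_table(study.metavars.reset_index(), path / "metavars.csv", meta)
    series = study.series.copy()
    series["date"] = pd.to_datetime(series["date"]).dt.strftime("%Y-%m-%d")
    write_table(series, path / "series.csv", meta)
    write_table(study.demography, path / "demography.csv", meta)
    bounds = study.age_group_bounds
    ag = pd.DataFrame([(k, lo, up) for k, (lo, up) in bounds.items()],
                      columns=["age_group", "lower", "upper"])
    write_table(ag, path / "age_groups.csv", meta)


# ---------------------------------------------------------------------------
# artifact tables
# ---------------------------------------------------------------------------

def _vech(m):
    return m[np.tril_indices(m.shape[0])]


def _unvech(v, p):
    m = np.zeros((p, p))
    m[np.tril_indices(p)] = v
    return m + np.tril(m, -1).T


def coefs_to_frame(coefs) -> pd.DataFrame:
    """Reduced coefficients as one wide table: location, age_group,
    age_value, spec fields, theta_1..p, vech(S)."""
    rows = []
    for c in coefs:
        p = c.theta.size
        row = {"location": c.location, "age_group": c.age_group,
               "age_value": c.age_value}
        if c.spec is not None and c.spec.resolved:
            row["exp_bmin"], row["exp_bmax"] = c.spec.exposure_boundary
            for j, k in enumerate(c.spec.exposure_knots):
                row[f"exp_knot{j+1}"] = k
            row["exp_degree"] = c.spec.exposure_degree
            row["max_lag"] = c.spec.max_lag
            row["n_lag_knots"] = c.spec.n_lag_knots
        for j in range(p):
            row[f"theta_{j+1}"] = c.theta[j]
        for j, v in enumerate(_vech(c.S)):
            row[f"s_{j+1}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_coefs(df) -> list:
    from .basis import CrossBasisSpec, ReducedCoef
    theta_cols = sorted([c for c in df.columns if c.startswith("theta_")],
                        key=lambda s: int(s.split("_")[1]))
    s_cols = sorted([c for c in df.columns if c.startswith("s_")],
                    key=lambda s: int(s.split("_")[1]))
    p = len(theta_cols)
    knot_cols = sorted([c for c in df.columns if c.startswith("exp_knot")])
    out = []
    for _, r in df.iterrows():
        spec = None
        if knot_cols and not pd.isna(r.get("exp_bmin", np.nan)):
            spec = CrossBasisSpec(
                exposure_degree=int(r["exp_degree"]),
                exposure_boundary=(r["exp_bmin"], r["exp_bmax"]),
                exposure_knots=tuple(r[c] for c in knot_cols),
                max_lag=int(r["max_lag"]), n_lag_knots=int(r["n_lag_knots"]))
        c = ReducedCoef(r["location"], r["age_group"],
                        r[theta_cols].to_numpy(dtype=float),
                        _unvech(r[s_cols].to_numpy(dtype=float), p),
                        spec=spec)
        c.age_value = float(r["age_value"]) if "age_value" in r else None
        out.append(c)
    return out
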