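"""Tables, fixtures, default shapes, configs and mesh export.

Shape-descriptor tables are CSV files with one row per measured papilla:

    genotype,Lhead_um,Lneck_um,Whead_um,Wneck_um

Per-genotype means and standard errors feed the analytic papilla builder.
Because the raw measurement tables are not redistributable, the package
ships a fixture generator that samples reproducible synthetic tables
around the published genotype means, and ``default_shapes`` builds the WT
and ktn1-5 prototypes directly from those means.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import PapillaShape, PinShape, ShapeDescriptors

DESCRIPTOR_COLUMNS = ["genotype", "Lhead_um", "Lneck_um", "Whead_um",
                      "Wneck_um"]

#: genotype mean descriptors (um).  Whead/Wneck are the published means;
#: Lhead/Lneck are synthetic stand-ins for the unavailable raw
#: measurements: Lhead = Whead/2 (near-hemispherical head) and a neck
#: two-thirds of the way down the observable cell.
DEFAULT_MEANS = {
    "WT": {"Lhead_um": 8.25, "Lneck_um": 40.0,
           "Whead_um": 16.50, "Wneck_um": 14.40},
    "ktn1-5": {"Lhead_um": 13.17, "Lneck_um": 40.0,
               "Whead_um": 26.34, "Wneck_um": 20.07},
}
#: standard errors of the mean (um); widths are the published SEMs, the
#: lengths are synthetic values of comparable relative spread
DEFAULT_SEMS = {
    "WT": {"Lhead_um": 0.30, "Lneck_um": 0.80,
           "Whead_um": 0.21, "Wneck_um": 0.27},
    "ktn1-5": {"Lhead_um": 0.50, "Lneck_um": 0.80,
               "Whead_um": 0.45, "Wneck_um": 0.45},
}


class SchemaError(ValueError):
    pass


def read_descriptor_table(path) -> pd.DataFrame:
    """Read a per-papilla measurement table, validating the schema."""
    df = pd.read_csv(path)
    missing = [c for c in DESCRIPTOR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"descriptor table misses columns {missing}")
    return df[DESCRIPTOR_COLUMNS]


def descriptor_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype mean and SEM of each descriptor.

    SEM is the sample standard deviation over sqrt(n); a single-row
    genotype has SEM 0 by convention.
    """
    missing = [c for c in DESCRIPTOR_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"descriptor table misses columns {missing}")
    value_cols = DESCRIPTOR_COLUMNS[1:]
    g = table.groupby("genotype")[value_cols]
    mean = g.mean()
    n = g.size()
    sem = (g.std(ddof=1).fillna(0.0)
           .div(np.sqrt(n), axis=0))
    out = mean.join(sem, lsuffix="_mean", rsuffix="_sem")
    out["n"] = n
    return out.reset_index()


def fixture_measurements(means: dict, sems: dict, n: int,
                         seed: int) -> pd.DataFrame:
    """Reproducible synthetic measurement table.

    Samples ``n`` papillae per genotype from normal distributions whose
    mean matches ``means`` and whose SEM (sd/sqrt(n)) matches ``sems``.
    Rows violating the bowling-pin constraints are redrawn.
    """
    if n < 2:
        raise ValueError("need n >= 2 rows per genotype")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, m in means.items():
        s = sems[genotype]
        made = 0
        while made < n:
            row = {"genotype": genotype}
            for col in DESCRIPTOR_COLUMNS[1:]:
                sd = s[col] * np.sqrt(n)
                row[col] = float(rng.normal(m[col], sd)) if sd > 0 \
                    else float(m[col])
            if (min(row[c] for c in DESCRIPTOR_COLUMNS[1:]) > 0
                    and row["Lneck_um"] > row["Lhead_um"]
                    and row["Wneck_um"] < row["Whead_um"]):
                rows.append(row)
                made += 1
    return pd.DataFrame(rows, columns=DESCRIPTOR_COLUMNS)


def shape_from_means(means: dict, genotype: str, **kw) -> PapillaShape:
    d = ShapeDescriptors(Lhead=means["Lhead_um"], Lneck=means["Lneck_um"],
                         Whead=means["Whead_um"], Wneck=means["Wneck_um"],
                         genotype=genotype)
    return PapillaShape(d, **kw)


def default_shapes(table: pd.DataFrame | None = None
                   ) -> dict[str, PapillaShape]:
    """The WT and ktn1-5 papilla prototypes.

    Built from the per-genotype means of ``table`` when one is supplied,
    otherwise from the packaged default means (synthetic stand-ins for
    the unavailable raw measurement table; provenance is recorded on the
    shape descriptors' genotype labels).
    """
    if table is not None:
        stats = descriptor_stats(table)
        means = {row["genotype"]:
                 {c: row[f"{c}_mean"] for c in DESCRIPTOR_COLUMNS[1:]}
                 for _, row in stats.iterrows()}
    else:
        means = DEFAULT_MEANS
    return {g: shape_from_means(m, g) for g, m in means.items()}


# --------------------------------------------------------------------------
# pin control points
# --------------------------------------------------------------------------

def read_control_points(path) -> pd.DataFrame:
    """Profile control-point table with columns ``index,x,y`` (x = radial
    ordinate, y = normalised height of each control point)."""
    df = pd.read_csv(path)
    for c in ("index", "x", "y"):
        if c not in df.columns:
            raise SchemaError(f"control-point table misses column {c!r}")
    return df.sort_values("index").reset_index(drop=True)


def pin_from_control_points(df: pd.DataFrame, W: float = 1.0,
                            H: float = 2.0) -> PinShape:
    """Build a pin surface from a control-point table (radial ordinates)."""
    return PinShape(control_values=df["x"].to_numpy(float), W=W, H=H)


# --------------------------------------------------------------------------
# mesh export
# --------------------------------------------------------------------------

def export_obj(surface, path, n_profile: int = 80,
               n_azimuth: int = 64) -> None:
    """Triangulated revolution mesh of a papilla or pin surface as OBJ."""
    if isinstance(surface, PapillaShape):
        ts = np.linspace(1e-4, surface.z_base, n_profile)
        def pt(t, th):
            return surface.surface_point(th, t)
    elif isinstance(surface, PinShape):
        ts = np.linspace(0.0, 1.0, n_profile)
        def pt(t, th):
            return surface.surface_point(t, th)
    else:
        raise TypeError("export_obj supports PapillaShape and PinShape")
    thetas = np.linspace(0.0, 2.0 * np.pi, n_azimuth, endpoint=False)
    lines = []
    for t in ts:
        for th in thetas:
            x, y, z = np.asarray(pt(t, th), float)
            lines.append(f"v {x:.6f} {y:.6f} {z:.6f}")
    def vid(i, j):
        return i * n_azimuth + (j % n_azimuth) + 1
    for i in range(n_profile - 1):
        for j in range(n_azimuth):
            lines.append(f"f {vid(i, j)} {vid(i + 1, j)} {vid(i + 1, j + 1)}")
            lines.append(f"f {vid(i, j)} {vid(i + 1, j + 1)} {vid(i, j + 1)}")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# configs and manifests
# --------------------------------------------------------------------------

def load_config(path) -> dict:
    """YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith((".json",)):
        return json.loads(text)
    return yaml.safe_load(text)


def run_manifest(config: dict, seed: int | None = None) -> dict:
    """Reproducibility manifest: config hash, seed, package version."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {"config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": seed, "papillasim_version": __version__}


def write_manifest(path, config: dict, seed: int | None = None) -> None:
    Path(path).write_text(json.dumps(run_manifest(config, seed), indent=2)
                          + "\n")
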