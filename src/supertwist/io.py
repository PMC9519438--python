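"""Readers, writers, configuration and the pipeline orchestrator.

File conventions: multi-model PDB (via biotite) holds pseudo-atom ribbons —
axis points as chain A and the two backbone strands as chains B and C,
1-based residue numbering; plain XYZ holds bare axis trajectories.  All bp
coordinates are 0-based half-open internally and 1-based closed in every
report and file output.  CSV output is comma-separated, '.' decimal, UTF-8
with a header row.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from . import __version__
from .conformation import apex_occupancy, detect_apices, polar_profile, radius_of_gyration
from .domains import loop_writhe_series, partition_loops
from .entropy import apex_state_count, entropy_reduction
from .minicircle import MinicircleSpec, build_planar_minicircle, strand_curves
from .synthetic import ribbon_from_contour
from .topology import (
    Contour,
    calibrate_lk0,
    extract_axis,
    superhelical_density,
    twist_global,
    writhe,
    site_accumulated_twist,
)

logger = logging.getLogger("supertwist")

__all__ = [
    "RunConfig",
    "TrajectoryInput",
    "read_structure",
    "read_xyz",
    "write_xyz",
    "write_ribbon_pdb",
    "load_config",
    "run_pipeline",
    "to_internal_range",
    "to_report_range",
]


# ---------------------------------------------------------------------------
# bp index conventions
# ---------------------------------------------------------------------------

def to_internal_range(report_range: tuple[int, int], n_bp: int) -> tuple[int, int]:
    """1-based closed [start, end] -> 0-based half-open [start, end)."""
    s, e = report_range
    if s < 1 or e < 1:
        raise ValueError("report ranges are 1-based")
    if s > n_bp or e > n_bp:
        raise ValueError(f"range ({s}, {e}) exceeds circle length {n_bp}")
    return ((s - 1) % n_bp, e % n_bp if e != n_bp else n_bp)


def to_report_range(internal_range: tuple[int, int], n_bp: int) -> tuple[int, int]:
    """0-based half-open [start, end) -> 1-based closed [start, end]."""
    s, e = internal_range
    return (s % n_bp + 1, (e - 1) % n_bp + 1)


# ---------------------------------------------------------------------------
# XYZ trajectories
# ---------------------------------------------------------------------------

def write_xyz(path: str | Path, trajectory: list[np.ndarray], comment: str = "") -> None:
    """Plain multi-frame XYZ with a pseudo-atom per axis point."""
    with open(path, "w", encoding="utf-8") as fh:
        for k, frame in enumerate(trajectory):
            pts = np.asarray(frame, dtype=float)
            fh.write(f"{len(pts)}\n")
            fh.write(f"frame {k} {comment}\n")
            for x, y, z in pts:
                fh.write(f"C {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: str | Path) -> list[np.ndarray]:
    """Read a multi-frame XYZ file; truncated or inconsistent files raise."""
    frames: list[np.ndarray] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError as err:
            raise ValueError(f"malformed XYZ atom count at line {pos + 1}") from err
        if pos + 1 + n >= len(lines) + 1 and len(lines) - pos - 2 < n:
            raise ValueError(
                f"truncated XYZ file: frame {len(frames)} promises {n} atoms"
            )
        block = lines[pos + 2 : pos + 2 + n]
        if len(block) < n:
            raise ValueError(
                f"truncated XYZ file: frame {len(frames)} promises {n} atoms"
            )
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        if frames and len(coords) != len(frames[0]):
            raise ValueError(
                f"inconsistent atom count in frame {len(frames)}: "
                f"{len(coords)} vs {len(frames[0])}"
            )
        frames.append(coords)
        pos += 2 + n
    if not frames:
        raise ValueError("empty XYZ file")
    return frames


# ---------------------------------------------------------------------------
# multi-model PDB of pseudo-atom ribbons
# ---------------------------------------------------------------------------

def write_ribbon_pdb(path: str | Path, ribbons, strand_radius: float = 9.0) -> None:
    """Multi-model PDB: axis as chain A, strand backbones as chains B and C."""
    if not isinstance(ribbons, (list, tuple)):
        ribbons = [ribbons]
    n = ribbons[0].n_bp
    n_atoms = 3 * n
    template = bst.AtomArray(n_atoms)
    template.chain_id = np.repeat(["A", "B", "C"], n)
    template.res_id = np.tile(np.arange(1, n + 1), 3)  # 1-based residues
    template.res_name = np.array(["DA"] * n_atoms)
    template.atom_name = np.array(["CA"] * n_atoms)
    template.element = np.array(["C"] * n_atoms)
    template.hetero = np.full(n_atoms, True)

    stack = bst.stack([template] * len(ribbons))
    for m, rib in enumerate(ribbons):
        s1, s2 = strand_curves(rib, strand_radius)
        stack.coord[m] = np.concatenate([rib.origins, s1, s2])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_structure(path: str | Path, fmt: str | None = None):
    """Read a multi-model PDB or XYZ trajectory.

    Returns ``(coords, metadata)`` where coords has shape
    (n_frames, n_atoms, 3).  For PDB, metadata carries chain ids, residue
    ids (1-based, as in the file) and atom names; for XYZ it is None.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        frames = read_xyz(path)
        return np.stack(frames), None
    if fmt == "pdb":
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
        if isinstance(stack, bst.AtomArray):
            stack = bst.stack([stack])
        meta = {
            "chain_id": stack.chain_id,
            "res_id": stack.res_id,
            "atom_name": stack.atom_name,
        }
        return stack.coord.copy(), meta
    raise ValueError(f"unknown trajectory format: {fmt!r}")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryInput:
    """One trajectory with its topoisomer label (integer turns)."""

    path: str
    lk: int
    label: str = ""
    replica: int = 1
    bare: bool = True       # protein-free: eligible for Lk0 calibration


@dataclass
class RunConfig:
    """Pipeline settings; binding-site range is 1-based closed in the file."""

    trajectories: list[TrajectoryInput]
    lk0: float | None = None            # calibrated from bare set when None
    site: tuple[int, int] | None = None
    window: int = 1
    bridge: tuple[int, int] | None = None     # 1-based positions in config
    discard_fraction: float = 2.0 / 3.0
    apex_smooth_window: int = 5
    apex_tolerance: int = 20
    entropy_fraction: float = 1.0
    temperature: float = 300.0
    seed: int = 0
    output_dir: str = "supertwist_out"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    trajs = [TrajectoryInput(**t) for t in raw.pop("trajectories")]
    for key in ("site", "bridge"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(trajectories=trajs, **raw)
    for t in cfg.trajectories:
        if not Path(t.path).exists():
            raise FileNotFoundError(f"trajectory not found: {t.path}")
    return cfg


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _analyse_trajectory(
    frames: np.ndarray,
    lk: int,
    lk0: float | None,
    site0: tuple[int, int] | None,
    window: int,
) -> pd.DataFrame:
    records = []
    for k, pts in enumerate(frames):
        contour = extract_axis(pts, window) if window > 1 else Contour(pts)
        rib = ribbon_from_contour(contour.points, lk)
        tw = twist_global(rib)
        wr = writhe(contour)
        lk_val = tw + wr
        rec = {
            "frame": k + 1,
            "lk": lk_val,
            "tw": tw,
            "wr": wr,
            "sigma": superhelical_density(lk_val, lk0) if lk0 else np.nan,
            "site_twist": site_accumulated_twist(rib, site0) if site0 else np.nan,
            "rg": radius_of_gyration(contour.points),
        }
        records.append(rec)
    return pd.DataFrame.from_records(records)


def run_pipeline(config: RunConfig) -> dict:
    """Run topology, shape, domain and entropy stages over all trajectories.

    Writes one topology CSV and one polar-profile CSV per trajectory, a
    calibration JSON (when >= 3 bare topoisomers are present), a domain
    report (when a bridge is configured) and an entropy JSON, plus a
    manifest with versions, seeds and the config hash.  Reruns with an
    unchanged config are byte-identical.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {
        "supertwist_version": __version__,
        "config_hash": chash,
        "seed": config.seed,
        "outputs": [],
        "defaults_applied": [],
    }

    results: dict = {"topology": {}, "calibration": None, "shape": {}, "domains": None}
    calib_points = []

    for traj in config.trajectories:
        name = traj.label or Path(traj.path).stem
        stage = f"topology[{name}]"
        try:
            coords, _ = read_structure(traj.path)
            n_keep = len(coords) - int(config.discard_fraction * len(coords))
            frames = coords[len(coords) - max(n_keep, 1):]
            n_bp = frames.shape[1]
            site0 = to_internal_range(config.site, n_bp) if config.site else None
            df = _analyse_trajectory(frames, traj.lk, config.lk0, site0, config.window)
        except Exception as err:
            raise RuntimeError(f"stage {stage} failed: {err}") from err
        df.insert(0, "config_hash", chash)
        topo_csv = out / f"topology_{name}.csv"
        df.to_csv(topo_csv, index=False, float_format="%.6f")
        manifest["outputs"].append(str(topo_csv))
        results["topology"][name] = df
        if traj.bare:
            calib_points.append((float(traj.lk), float(df["wr"].mean())))

        # shape stage
        try:
            contours = [
                extract_axis(p, config.window) if config.window > 1 else Contour(p)
                for p in frames
            ]
            site_bp = site0[0] if site0 else 0
            prof = polar_profile(contours, site=site_bp)
            calls = [
                detect_apices(prof.distances[k], config.apex_smooth_window, frame_index=k)
                for k in range(len(contours))
            ]
            occ = apex_occupancy(calls, site_bp, config.apex_tolerance, n_bp)
            shape_df = pd.DataFrame(
                {
                    "bp": np.arange(1, n_bp + 1),
                    "mean_distance": prof.mean,
                    "sd_distance": prof.sd,
                    "angle": prof.angles,
                }
            )
            shape_df.insert(0, "config_hash", chash)
            shape_csv = out / f"shape_{name}.csv"
            shape_df.to_csv(shape_csv, index=False, float_format="%.6f")
            manifest["outputs"].append(str(shape_csv))
            results["shape"][name] = {"profile": prof, "apex_occupancy": occ}
        except Exception as err:
            raise RuntimeError(f"stage shape[{name}] failed: {err}") from err

        # domain stage (first trajectory with a configured bridge)
        if config.bridge is not None and results["domains"] is None:
            try:
                b0 = (config.bridge[0] - 1) % n_bp, (config.bridge[1] - 1) % n_bp
                part = partition_loops(contours[0], b0)
                report = loop_writhe_series(contours, part)
                dom_df = pd.DataFrame(
                    {
                        "frame": np.arange(1, len(contours) + 1),
                        "wr_total": report.wr_total,
                        "wr_loop1": report.wr_loop1,
                        "wr_loop2": report.wr_loop2,
                        "cross_wr": report.cross_wr,
                    }
                )
                dom_df.insert(0, "config_hash", chash)
                dom_csv = out / f"domains_{name}.csv"
                dom_df.to_csv(dom_csv, index=False, float_format="%.6f")
                summary = {
                    "config_hash": chash,
                    "bridge_1based": list(config.bridge),
                    "loop_bp": list(part.loop_bp),
                    "r_squared_loops": report.r_squared_loops,
                    "slope_sign_loops": report.slope_sign_loops,
                    "r_squared_total_vs_loop": list(report.r_squared_total_vs_loop),
                    "writhe_share": list(report.writhe_share),
                }
                (out / "domains_summary.json").write_text(
                    json.dumps(summary, indent=2, sort_keys=True)
                )
                manifest["outputs"] += [str(dom_csv), str(out / "domains_summary.json")]
                results["domains"] = report
            except Exception as err:
                raise RuntimeError(f"stage domains[{name}] failed: {err}") from err

    if config.lk0 is None and len({p[0] for p in calib_points}) >= 3:
        cal = calibrate_lk0(calib_points)
        cal_payload = {
            "config_hash": chash,
            "lk0": cal.lk0,
            "slope": cal.slope,
            "intercept": cal.intercept,
            "r_squared": cal.r_squared,
            "points": cal.points,
        }
        (out / "calibration.json").write_text(json.dumps(cal_payload, indent=2, sort_keys=True))
        manifest["outputs"].append(str(out / "calibration.json"))
        results["calibration"] = cal
    elif config.lk0 is None:
        logger.warning("fewer than 3 bare topoisomers: Lk0 not calibrated")

    if config.trajectories:
        first_frames, _ = read_structure(config.trajectories[0].path)
        w = apex_state_count(first_frames.shape[1], config.entropy_fraction)
        est = entropy_reduction(w, 1, config.temperature)
        ent_payload = {
            "config_hash": chash,
            "w_states": est.w_states,
            "delta_s_kb": est.delta_s_kb,
            "t_delta_s_kcal": est.t_delta_s_kcal,
            "temperature": est.temperature,
        }
        (out / "entropy.json").write_text(json.dumps(ent_payload, indent=2, sort_keys=True))
        manifest["outputs"].append(str(out / "entropy.json"))
        results["entropy"] = est

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results


# ---------------------------------------------------------------------------
# builder output convenience
# ---------------------------------------------------------------------------

def write_built_minicircle(
    path: str | Path, n_bp: int, lk: int, rise: float = 3.4, strand_radius: float = 9.0
) -> None:
    """Build a planar topoisomer and write it as PDB or XYZ by extension."""
    rib = build_planar_minicircle(MinicircleSpec(n_bp=n_bp, lk=lk, rise=rise))
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        write_ribbon_pdb(path, rib, strand_radius)
    elif path.suffix.lower() == ".xyz":
        write_xyz(path, [rib.origins], comment=f"planar minicircle lk={lk}")
    else:
        raise ValueError("output must end in .pdb or .xyz")
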