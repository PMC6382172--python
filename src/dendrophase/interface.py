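"""File formats and command-line front end.

All event and trace tables are comma-separated text with ``#`` comments.
Times are milliseconds unless the file declares ``# units: s`` in a comment
header, in which case values are converted on read.  Results are written as
JSON with units embedded in the key names.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import click
import numpy as np

from . import __version__
from .cable_model import PhaseFreqData, ccf_peak, fit_electrotonic
from .entrainment import (
    bootstrap_threshold,
    build_map,
    circular_stat,
    effective_phases,
    find_fixed_points,
    simulate_tp_curve,
)
from .population import compute_psth, fit_psth, measure_rates
from .prc import PulseTrain, SpikeTrain, TriangularPRC, bin_pulses, estimate_prc, fit_triangle
from .synthetic_data import GeneratorConfig, gen_barrage, gen_barrage_sweeps, gen_cable_sweep, gen_pacemaker

__all__ = [
    "read_spike_file",
    "read_pulse_file",
    "read_trace",
    "read_phase_table",
    "write_spike_file",
    "write_results",
    "cli_main",
]


def _read_rows(path: str | Path, n_cols: int) -> tuple[np.ndarray, float]:
    """Parse a delimited text file; returns (values, time-unit factor to ms)."""
    path = Path(path)
    unit_factor = 1.0
    rows: list[list[float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("#"):
                if "units:" in line and line.split("units:")[1].strip() in ("s", "sec", "seconds"):
                    unit_factor = 1000.0
                continue
            if not line:
                continue
            parts = line.replace("\t", ",").split(",")
            try:
                vals = [float(p) for p in parts if p != ""]
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed row {line!r}") from exc
            if len(vals) != n_cols:
                raise ValueError(
                    f"{path}:{ln}: expected {n_cols} columns, got {len(vals)}"
                )
            if not all(np.isfinite(vals)):
                raise ValueError(f"{path}:{ln}: non-finite value")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no events found")
    return np.asarray(rows, dtype=float), unit_factor


def read_spike_file(path: str | Path, window_ms: tuple[float, float] | None = None) -> SpikeTrain:
    """Spike times, one per row (ms, or s with a ``# units: s`` header)."""
    arr, fac = _read_rows(path, 1)
    times = arr[:, 0] * fac
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: spike times are not strictly increasing")
    if window_ms is None:
        window_ms = (float(times[0]), float(times[-1]) + 1e-9)
    return SpikeTrain(times=times, window=window_ms)


def read_pulse_file(path: str | Path, width_ms: float = 0.5) -> PulseTrain:
    """Pulse onsets, one per row; the pulse width is supplied by the caller."""
    arr, fac = _read_rows(path, 1)
    return PulseTrain(onsets=arr[:, 0] * fac, width=width_ms)


def read_trace(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Two-column ``time,value`` trace; returns (t_ms, values, dt_ms).

    The time column must be uniformly sampled to 1e-9 relative tolerance.
    """
    arr, fac = _read_rows(path, 2)
    t = arr[:, 0] * fac
    dt = np.diff(t)
    if len(dt) == 0:
        raise ValueError(f"{path}: trace needs at least 2 samples")
    if np.any(np.abs(dt - dt[0]) > 1e-9 * abs(dt[0])):
        raise ValueError(f"{path}: non-uniform sampling in time column")
    return t, arr[:, 1], float(dt[0])


def read_phase_table(path: str | Path) -> list[PhaseFreqData]:
    """Phase-versus-frequency table ``freq_hz,phase_cycles,condition`` with header."""
    path = Path(path)
    by_cond: dict[str, list[tuple[float, float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if parts[0].lower().startswith("freq"):
                continue
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected freq_hz,phase_cycles,condition")
            try:
                f, ph = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed row {line!r}") from exc
            by_cond.setdefault(parts[2], []).append((f, ph))
    if not by_cond:
        raise ValueError(f"{path}: no events found")
    out = []
    for cond, rows in by_cond.items():
        rows.sort()
        f, ph = zip(*rows)
        out.append(PhaseFreqData(np.array(f), np.array(ph), condition=cond))
    return out


def write_spike_file(path: str | Path, spikes: SpikeTrain) -> None:
    with open(path, "w") as fh:
        fh.write("# spike times, ms\n")
        for t in spikes.times:
            fh.write(f"{t:.6f}\n")


def write_results(path: str | Path, record: dict) -> None:
    """JSON result record, annotated with the package version."""
    record = dict(record)
    record.setdefault("dendrophase_version", __version__)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
def cli() -> None:
    """Dendritic filtering, PRC and entrainment analysis of pacemaker neurons."""


@cli.command("fit-cable")
@click.option("--data", "data_path", required=True, type=click.Path(exists=True))
@click.option("--fmin", default=6.0, show_default=True)
@click.option("--fmax", default=16.0, show_default=True)
@click.option("--radius-um", default=None, type=float, help="Outer stimulation radius (um)")
@click.option("--out", "out_path", required=True, type=click.Path())
def cli_fit_cable(data_path, fmin, fmax, radius_um, out_path):
    """Fit (tau, rho) of the cable model to a phase-vs-frequency table."""
    results = {}
    for data in read_phase_table(data_path):
        fit = fit_electrotonic(data, stim_radius_known=radius_um, fmin_hz=fmin, fmax_hz=fmax)
        entry = {
            "tau_ms": fit.tau_ms,
            "rho": fit.rho,
            "rmse_cycles": fit.rmse_cycles,
        }
        if fit.lam is not None:
            entry["lambda_um"] = fit.lam
        results[data.condition or "all"] = entry
    write_results(out_path, {"fit": results, "config": {"fmin_hz": fmin, "fmax_hz": fmax}})
    click.echo(json.dumps(results, indent=2))


@cli.command("estimate-prc")
@click.option("--spikes", "spikes_path", required=True, type=click.Path(exists=True))
@click.option("--pulses", "pulses_path", required=True, type=click.Path(exists=True))
@click.option("--window", nargs=2, type=float, default=(4000.0, 9000.0), show_default=True,
              help="Steady-state analysis window (ms)")
@click.option("--pulse-width", default=0.5, show_default=True)
@click.option("--force-zero-ends", is_flag=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def cli_estimate_prc(spikes_path, pulses_path, window, pulse_width, force_zero_ends, out_path):
    """Estimate the PRC from a barrage session and fit the acute triangle."""
    spikes = read_spike_file(spikes_path).restricted(*window)
    pulses = read_pulse_file(pulses_path, width_ms=pulse_width)
    keep = (pulses.onsets >= window[0]) & (pulses.onsets <= window[1])
    pulses = PulseTrain(onsets=pulses.onsets[keep], width=pulses.width)
    est = estimate_prc(bin_pulses(spikes, pulses))
    tri = fit_triangle(est.z, est.phases, force_zero_ends=force_zero_ends)
    record = {
        "theta": tri.theta,
        "amp_per_pulse": tri.amp,
        "offset": tri.offset,
        "mean_isi_ms": est.mean_isi_ms,
        "z_per_pulse": est.z.tolist(),
        "phases": est.phases.tolist(),
        "config": {"window_ms": list(window), "force_zero_ends": force_zero_ends},
    }
    write_results(out_path, record)
    click.echo(f"theta={tri.theta:.4f} amp={tri.amp:.5f} offset={tri.offset:.5f}")


@cli.command("psth")
@click.option("--manifest", "manifest_path", required=True, type=click.Path(exists=True),
              help="JSON manifest: [{'spikes': path, 'onsets': [ms, ...]}, ...]")
@click.option("--bin-ms", default=4.0, show_default=True)
@click.option("--fit", "do_fit", is_flag=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def cli_psth(manifest_path, bin_ms, do_fit, out_path):
    """Compute (and optionally fit) the PSTH around barrage onset."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = Path(manifest_path).parent
    trains, onsets = [], []
    for entry in manifest:
        trains.append(read_spike_file(base / entry["spikes"]))
        onsets.append(entry["onsets"])
    psth = compute_psth(trains, onsets, bin_ms=bin_ms)
    record = {
        "bin_start_ms": psth.bin_edges[:-1].tolist(),
        "rate_hz": psth.rate.tolist(),
        "n_sweeps": psth.n_sweeps,
        "config": {"bin_ms": bin_ms},
    }
    if do_fit:
        f_base, f_steady = measure_rates(psth)
        params = fit_psth(psth, f_base, f_steady)
        record["fit"] = {
            "sigma_per_sqrt_s": params.sigma,
            "theta": params.theta,
            "f_base_hz": f_base,
            "f_steady_hz": f_steady,
        }
        click.echo(f"sigma={params.sigma:.4f} theta={params.theta:.4f}")
    write_results(out_path, record)


@cli.command("entrain")
@click.option("--session", "session_path", required=True, type=click.Path(exists=True),
              help="JSON sidecar: {'spikes': path, 'f_hz': .., 't_stim_start_ms': ..}")
@click.option("--threshold-boot", default=10000, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def cli_entrain(session_path, threshold_boot, seed, out_path):
    """Circular statistics of effective spike phases in an entrainment session."""
    with open(session_path) as fh:
        meta = json.load(fh)
    spikes = read_spike_file(Path(session_path).parent / meta["spikes"])
    psi = effective_phases(spikes, meta["f_hz"], meta.get("t_stim_start_ms", 0.0))
    stat = circular_stat(psi)
    thr = bootstrap_threshold(n=100, reps=threshold_boot, seed=seed)
    record = {
        "n_spikes": stat.n,
        "locking_amplitude": stat.amplitude,
        "locking_phase_cycles": stat.phase,
        "threshold_95": thr,
        "entrained": stat.amplitude > thr,
        "config": {"f_hz": meta["f_hz"], "reps": threshold_boot, "seed": seed},
    }
    write_results(out_path, record)
    click.echo(
        f"amplitude={stat.amplitude:.3f} phase={stat.phase:.3f} "
        f"threshold={thr:.3f} entrained={stat.amplitude > thr}"
    )


@cli.command("predict-locking")
@click.option("--theta", required=True, type=float)
@click.option("--a", "--A", "amp", default=5.0, show_default=True)
@click.option("--f", "f_hz", default=7.0, show_default=True)
@click.option("--f0", "f0_hz", default=7.0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def cli_predict_locking(theta, amp, f_hz, f0_hz, out_path):
    """Predicted locking phase from the PRC-based phase model."""
    prc = TriangularPRC(theta=theta)
    tp_fn = simulate_tp_curve(prc, f_hz, f0_hz, amp)
    rmap = build_map(tp_fn, 1000.0 / f_hz, provenance="simulated")
    fps = find_fixed_points(rmap)
    record = {
        "fixed_points": [
            {"psi": fp.psi, "slope": fp.slope, "stable": fp.stable}
            for fp in fps
        ],
        "stable_phases": [fp.psi for fp in fps if fp.stable],
        "config": {"theta": theta, "A": amp, "f_hz": f_hz, "f0_hz": f0_hz},
    }
    write_results(out_path, record)
    for fp in fps:
        click.echo(f"psi*={fp.psi:.4f} slope={fp.slope:.3f} stable={fp.stable}")


@cli.command("simulate")
@click.argument("kind", type=click.Choice(["barrage", "pacemaker", "cable-sweep"]))
@click.option("--seed", default=0, show_default=True)
@click.option("--out-dir", required=True, type=click.Path())
@click.option("--theta", default=0.8, show_default=True)
@click.option("--duration-s", default=12.0, show_default=True)
def cli_simulate(kind, seed, out_dir, theta, duration_s):
    """Generate synthetic inputs in the same formats the analysis commands read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = GeneratorConfig(seed=seed, prc=TriangularPRC(theta=theta))
    if kind == "barrage":
        pulses = gen_barrage(cfg, duration_ms=duration_s * 1000.0)
        with open(out / "pulses.csv", "w") as fh:
            fh.write("# pulse onsets, ms\n")
            for t in pulses.onsets:
                fh.write(f"{t:.6f}\n")
        click.echo(f"wrote {len(pulses.onsets)} pulses to {out / 'pulses.csv'}")
    elif kind == "pacemaker":
        pulses = gen_barrage(
            cfg, duration_ms=cfg.stim_s * 1000.0, t_start_ms=cfg.baseline_s * 1000.0
        )
        spikes = gen_pacemaker(cfg, pulses)
        write_spike_file(out / "spikes.csv", spikes)
        click.echo(f"wrote {len(spikes.times)} spikes to {out / 'spikes.csv'}")
    else:
        sweeps, truth = gen_cable_sweep(cfg, [6.0, 8.0, 10.0, 12.0, 14.0, 16.0])
        for (t, stim, resp), f in zip(sweeps, truth["freqs_hz"]):
            with open(out / f"sweep_{f:g}hz.csv", "w") as fh:
                fh.write("# time_ms,response\n")
                for a, b in zip(t[::1], resp[::1]):
                    fh.write(f"{a:.4f},{b:.6f}\n")
        write_results(out / "truth.json", truth)
        click.echo(f"wrote {len(sweeps)} sweeps to {out}")


def cli_main(argv: list[str] | None = None) -> int:
    """Entry point; returns the process exit code instead of raising SystemExit."""
    try:
        cli.main(args=argv, standalone_mode=False)
        return 0
    except SystemExit as exc:  # --help and friends
        return int(exc.code or 0)
    except click.ClickException as exc:
        exc.show(file=sys.stderr)
        return exc.exit_code
    except (ValueError, FileNotFoundError, RuntimeError) as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 1


if __name__ == "__main__":
    raise SystemExit(cli_main())
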