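"""Model/Results interface tying the pipeline together.

:class:`ThetaTravelingWave` is built from a :class:`~thetatravel.io.Recording`
(or a session directory, or a simulation config); ``fit()`` runs artifact
rejection, theta-epoch selection, both phase estimators, the
traveling-wave metrics, waveform-asymmetry summaries, conduction-delay
profiles with the asymmetry correction, and (given enough cycles) the
coupled-oscillator vs fixed-delay mechanism test, returning a
:class:`TravelingWaveResults` with a ``summary()`` table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import asymmetry as asym_mod
from . import delay as delay_mod
from . import preprocess, travelwave
from .io import EpochSet, Recording, read_recording, write_recording
from .phase import hilbert_phase, unwrap_phase_deg, waveform_phase
from .sim import GroundTruth, SimConfig, simulate_session
from .stats import _to_jsonable, bootstrap_median_ci

log = logging.getLogger(__name__)


@dataclass
class TravelingWaveResults:
    """Fitted traveling-wave quantities for one session."""

    channels: list
    positions_mm: np.ndarray
    epochs: EpochSet
    fraction_removed: float
    phase_offsets_deg: dict
    gradient: travelwave.GradientFit
    mrl: dict
    mrl_fit: travelwave.GradientFit
    coherence: np.ndarray
    coherence_fit: travelwave.GradientFit
    relative_power: np.ndarray
    power_fit: travelwave.GradientFit
    asymmetry: pd.DataFrame  # per-channel medians (rise_decay, peak_trough)
    asymmetry_rd_fit: travelwave.GradientFit
    delay_profile: delay_mod.DelayProfile
    asym_delay_ms_per_mm: float
    corrected_delay_ms_per_mm: float
    corrected_ci: tuple
    mechanism: delay_mod.CouplingTestResult | None
    per_cycle: pd.DataFrame  # peak-reference delays + corrections
    n_cycles: int
    meta: dict = field(default_factory=dict)

    # -- headline quantities -------------------------------------------------

    def headline(self) -> dict:
        """Flat dict of the figure-level quantities for report pooling."""
        med = self.delay_profile.medians
        out = {
            "gradient_deg_per_mm": self.gradient.slope,
            "gradient_r2": self.gradient.r2,
            "mrl_slope_per_mm": self.mrl_fit.slope,
            "coherence_slope_per_mm": self.coherence_fit.slope,
            "rel_power_slope_per_mm": self.power_fit.slope,
            "asym_rd_dorsal": float(self.asymmetry["rise_decay"].iloc[0]),
            "asym_rd_ventral": float(self.asymmetry["rise_decay"].iloc[-1]),
            "asym_pt_dorsal": float(self.asymmetry["peak_trough"].iloc[0]),
            "asym_pt_ventral": float(self.asymmetry["peak_trough"].iloc[-1]),
            "delay_peak_ms_per_mm": med[0][0],
            "delay_falling_ms_per_mm": med[90][0],
            "delay_trough_ms_per_mm": med[180][0],
            "delay_rising_ms_per_mm": med[270][0],
            "asym_delay_ms_per_mm": self.asym_delay_ms_per_mm,
            "corrected_delay_ms_per_mm": self.corrected_delay_ms_per_mm,
            "n_cycles": self.n_cycles,
        }
        if self.mechanism is not None:
            out.update({
                "slope_abs_ms_per_hz": self.mechanism.slope_abs,
                "slope_rel_pct_per_hz": self.mechanism.slope_rel,
                "rho_abs": self.mechanism.rho_abs,
                "rho_rel": self.mechanism.rho_rel,
                "mechanism": self.mechanism.classification,
            })
        return out

    def summary(self) -> str:
        """Human-readable summary table."""
        h = self.headline()
        lines = [
            "Traveling theta wave analysis",
            "=" * 64,
            f"channels: {len(self.channels)}   span: "
            f"{self.positions_mm[-1] - self.positions_mm[0]:.3f} mm   "
            f"theta epochs: {self.epochs.total_s:.1f} s   "
            f"artifacts removed: {100 * self.fraction_removed:.2f} %",
            "-" * 64,
            "Hilbert phase gradient "
            f"{h['gradient_deg_per_mm']:8.2f} deg/mm   r2 = {h['gradient_r2']:.4f}",
            f"phase-locking slope    {h['mrl_slope_per_mm']:8.4f} /mm",
            f"coherence slope        {h['coherence_slope_per_mm']:8.4f} /mm",
            f"rel. power slope       {h['rel_power_slope_per_mm']:8.4f} /mm",
            "-" * 64,
            "waveform asymmetry (median log10 ratio, dorsal -> ventral)",
            f"  rise/decay  {h['asym_rd_dorsal']:+.3f} -> {h['asym_rd_ventral']:+.3f}",
            f"  peak/trough {h['asym_pt_dorsal']:+.3f} -> {h['asym_pt_ventral']:+.3f}",
            "-" * 64,
            "conduction delay (ms/mm, median over cycles)",
            f"  peak {h['delay_peak_ms_per_mm']:6.2f}   "
            f"falling {h['delay_falling_ms_per_mm']:6.2f}   "
            f"trough {h['delay_trough_ms_per_mm']:6.2f}   "
            f"rising {h['delay_rising_ms_per_mm']:6.2f}",
            f"  waveform-related delay  {h['asym_delay_ms_per_mm']:6.2f} ms/mm",
            f"  asymmetry-corrected     {h['corrected_delay_ms_per_mm']:6.2f} ms/mm "
            f"[{self.corrected_ci[0]:.2f}, {self.corrected_ci[1]:.2f}]",
        ]
        if self.mechanism is not None:
            m = self.mechanism
            lines += [
                "-" * 64,
                f"mechanism test over {m.n_cycles} cycles:",
                f"  abs delay vs freq  {m.slope_abs:+.3f} ms/Hz  "
                f"CI [{m.ci_abs[0]:+.3f}, {m.ci_abs[1]:+.3f}]  rho={m.rho_abs:+.3f}",
                f"  rel delay vs freq  {m.slope_rel:+.3f} %/Hz   "
                f"CI [{m.ci_rel[0]:+.3f}, {m.ci_rel[1]:+.3f}]  rho={m.rho_rel:+.3f}",
                f"  classification: {m.classification}",
            ]
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_json(self, path=None) -> dict:
        out = _to_jsonable({
            "headline": self.headline(),
            "phase_offsets_deg": self.phase_offsets_deg,
            "delay_profile": {
                str(ph): {"median": m, "ci": [lo, hi],
                          "n": self.delay_profile.n_cycles[ph]}
                for ph, (m, lo, hi) in self.delay_profile.medians.items()
            },
            "delay_phase_trend": (
                None if self.delay_profile.trend is None else {
                    "slope_ms_per_mm_per_deg": self.delay_profile.trend.slope,
                    "r2": self.delay_profile.trend.r2,
                }
            ),
            "corrected_ci": list(self.corrected_ci),
            "meta": self.meta,
        })
        if path is not None:
            Path(path).write_text(json.dumps(out, indent=1))
        return out

    def plot(self, path=None):
        """Four-panel overview figure (offsets, asymmetry, delay profile,
        delay vs frequency)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 2, figsize=(9, 7))
        ax = axes[0, 0]
        x = self.positions_mm
        y = [self.phase_offsets_deg[ch] for ch in self.channels]
        ax.plot(x, y, "o")
        ax.plot(x, self.gradient.predict(x), "-")
        ax.set_xlabel("distance (mm)")
        ax.set_ylabel("phase offset (deg)")
        ax.set_title(f"{self.gradient.slope:.1f} deg/mm, r2={self.gradient.r2:.2f}")

        ax = axes[0, 1]
        ax.plot(x, self.asymmetry["rise_decay"], "o-", label="rise/decay")
        ax.plot(x, self.asymmetry["peak_trough"], "s-", label="peak/trough")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("distance (mm)")
        ax.set_ylabel("median log10 ratio")
        ax.legend()
        ax.set_title("waveform asymmetry")

        ax = axes[1, 0]
        phases = [90, 180, 270, 0]
        labels = ["fall", "trough", "rise", "peak"]
        meds = [self.delay_profile.medians[p] for p in phases]
        ax.errorbar(
            [90, 180, 270, 360], [m[0] for m in meds],
            yerr=[[m[0] - m[1] for m in meds], [m[2] - m[0] for m in meds]],
            fmt="o-",
        )
        ax.set_xticks([90, 180, 270, 360], labels)
        ax.set_ylabel("conduction delay (ms/mm)")
        ax.set_title("delay by reference phase")

        ax = axes[1, 1]
        if len(self.per_cycle):
            f = self.per_cycle["freq_hz"]
            ax.plot(f, self.per_cycle["corrected"], ".", ms=2, alpha=0.4)
            if self.mechanism is not None:
                ff = np.linspace(f.min(), f.max(), 10)
                fit = np.polyfit(f, self.per_cycle["corrected"], 1)
                ax.plot(ff, np.polyval(fit, ff), "r-")
                ax.set_title(f"mechanism: {self.mechanism.classification}")
        ax.set_xlabel("theta frequency (Hz)")
        ax.set_ylabel("corrected delay (ms/mm)")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=110)
            plt.close(fig)
        return fig


class ThetaTravelingWave:
    """Traveling-wave model of a multichannel theta recording.

    Parameters
    ----------
    recording : Recording
    amp_criterion_uV : float, optional
        Theta-epoch amplitude criterion; defaults to 400 µV rescaled by
        the generator amplitude when the recording carries a simulation
        config, otherwise 400 µV.
    n_boot : int
        Bootstrap resamples for medians and mechanism-test CIs.
    seed : int
        Seed for all bootstrap resampling.
    """

    def __init__(self, recording: Recording, amp_criterion_uV: float | None = None,
                 n_boot: int = 500, seed: int = 0,
                 ref_channel: str | None = None):
        self.recording = recording
        if amp_criterion_uV is None:
            sim_cfg = recording.meta.get("sim_config")
            if sim_cfg:
                amp_criterion_uV = preprocess.scaled_amplitude_criterion(
                    sim_cfg["theta_amp_uV"]
                )
            else:
                amp_criterion_uV = preprocess.DEFAULT_AMP_UV
        self.amp_criterion_uV = amp_criterion_uV
        self.n_boot = n_boot
        self.seed = seed
        self.ref_channel = ref_channel or recording.channel_ids[0]

    @classmethod
    def from_session_dir(cls, path, **kwargs) -> "ThetaTravelingWave":
        return cls(read_recording(path), **kwargs)

    @classmethod
    def simulate(cls, config: SimConfig, **kwargs):
        """Simulate a session and build the model on it.

        Returns (model, ground_truth)."""
        recording, truth = simulate_session(config)
        return cls(recording, **kwargs), truth

    # -- fitting -------------------------------------------------------------

    def fit(self, min_cycles_mechanism: int = 500) -> TravelingWaveResults:
        rec = self.recording
        channels = list(rec.channel_ids)
        positions = {ch: float(x) for ch, x in zip(channels, rec.positions_mm)}
        ref = self.ref_channel

        mask = preprocess.remove_artifacts_recording(rec)
        combined = mask.include.all(axis=0)
        ref_idx = channels.index(ref)
        epochs = preprocess.select_theta_epochs(
            rec.samples[ref_idx], rec.fs_hz, combined, self.amp_criterion_uV
        )
        if len(epochs) == 0:
            raise RuntimeError("no high-amplitude theta epochs selected")

        # Hilbert-phase metrics
        phases = {
            ch: hilbert_phase(rec.samples[i], rec.fs_hz, epochs, channel=ch)
            for i, ch in enumerate(channels)
        }
        offsets, _ = travelwave.phase_offsets(phases, ref)
        gradient = travelwave.phase_gradient(offsets, positions)
        mrl = {
            ch: travelwave.phase_locking(phases[ch].phase_deg,
                                         phases[ref].phase_deg)
            for ch in channels
        }
        mrl_fit = travelwave.metric_vs_distance(
            [mrl[ch] for ch in channels], rec.positions_mm
        )
        coherence = travelwave.coherence_matrix(rec, combined)
        coherence_fit = travelwave.metric_vs_distance(
            coherence[ref_idx], rec.positions_mm
        )
        power = travelwave.theta_band_power(rec, combined)
        rel_power = travelwave.relative_power(power)
        power_fit = travelwave.metric_vs_distance(rel_power, rec.positions_mm)

        # waveform-phase cycles and asymmetry
        cycles_by_channel = {}
        for i, ch in enumerate(channels):
            _, cycles = waveform_phase(rec.samples[i], rec.fs_hz, epochs,
                                       channel=ch)
            cycles_by_channel[ch] = cycles
        asym_rows = []
        for ch in channels:
            a = asym_mod.channel_asymmetry(cycles_by_channel[ch])
            asym_rows.append({
                "channel": ch, "position_mm": positions[ch],
                "rise_decay": a.rise_decay, "peak_trough": a.peak_trough,
                "n_cycles": len(cycles_by_channel[ch]),
            })
        asym_table = pd.DataFrame(asym_rows)
        asym_fit = travelwave.fit_gradient(
            asym_table["position_mm"], asym_table["rise_decay"]
        )

        # conduction delays
        profile, tables = delay_mod.delay_profile(
            cycles_by_channel, positions, ref, n_boot=self.n_boot,
            seed=self.seed,
        )
        asym_slope, asym_cycles = delay_mod.asymmetry_delay_gradient(
            cycles_by_channel, positions, ref
        )
        corrected_med, per_cycle = delay_mod.corrected_delay(
            tables[0], asym_cycles
        )
        if len(per_cycle):
            _, lo, hi = bootstrap_median_ci(
                per_cycle["corrected"], n_boot=self.n_boot, seed=self.seed
            )
        else:
            lo = hi = np.nan
        per_cycle = per_cycle.rename(columns={
            "period_ms_obs": "period_ms", "freq_hz_obs": "freq_hz",
        })

        # cycle frequency from the reference channel's elapsed Hilbert
        # phase (anchor noise cancels to first order there), with the
        # smoothed across-channel consensus period as fallback
        cons = delay_mod.consensus_period(cycles_by_channel, ref)
        per_cycle = per_cycle.merge(cons, on="t_ref", how="left")
        per_cycle = per_cycle.sort_values("t_ref").reset_index(drop=True)
        unwrapped = unwrap_phase_deg(phases[ref].phase_deg)
        t_eff = delay_mod.hilbert_cycle_period(
            unwrapped, rec.fs_hz, per_cycle["t_ref"].values,
            per_cycle["period_ms"].values,
        )
        fallback = (per_cycle["consensus_period_ms"]
                    .rolling(5, center=True, min_periods=1).median())
        t_eff = np.where(np.isfinite(t_eff), t_eff, fallback)
        # smooth over ~1 s: phase noise makes single-cycle frequency
        # fluctuate without moving the (coupled) chain's delays, which
        # would dilute and rotate the delay-vs-frequency regressions
        per_cycle["period_smooth_ms"] = (
            pd.Series(t_eff).rolling(9, center=True, min_periods=1).median()
        )
        mechanism = None
        if len(per_cycle) >= min_cycles_mechanism:
            mechanism = delay_mod.mechanism_test(
                per_cycle["corrected"], per_cycle["period_smooth_ms"],
                n_boot=self.n_boot, seed=self.seed,
                min_cycles=min_cycles_mechanism,
            )
        else:
            log.info("mechanism test skipped: %d cycles", len(per_cycle))

        return TravelingWaveResults(
            channels=channels,
            positions_mm=rec.positions_mm.copy(),
            epochs=epochs,
            fraction_removed=float(1 - combined.mean()),
            phase_offsets_deg=offsets,
            gradient=gradient,
            mrl=mrl,
            mrl_fit=mrl_fit,
            coherence=coherence,
            coherence_fit=coherence_fit,
            relative_power=rel_power,
            power_fit=power_fit,
            asymmetry=asym_table,
            asymmetry_rd_fit=asym_fit,
            delay_profile=profile,
            asym_delay_ms_per_mm=asym_slope,
            corrected_delay_ms_per_mm=corrected_med,
            corrected_ci=(float(lo), float(hi)),
            mechanism=mechanism,
            per_cycle=per_cycle,
            n_cycles=int(len(per_cycle)),
            meta={"amp_criterion_uV": self.amp_criterion_uV,
                  "ref_channel": ref,
                  "n_epochs": len(epochs)},
        )


# ---------------------------------------------------------------------------
# session orchestration


def _stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage seed fan-out (counter-based, < 2^31)."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0]
               % (2 ** 31))


def run_all(config: SimConfig, out_dir, seed: int | None = None,
            analyze_mua: bool = False) -> dict:
    """simulate -> preprocess -> analyze -> report for one session.

    Writes the recording (flat binary + sidecar), ground truth
    (trajectories down-sampled to 100 Hz), spike table when MUA is
    simulated, selected epochs, per-cycle delay table, results JSON, the
    summary text, and a provenance block (config hash and stage seeds).
    Deterministic for fixed config and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = SimConfig.from_dict({**config.to_dict(),
                                      "seed": _stage_seed(seed, 0)})
    recording, truth = simulate_session(config)
    write_recording(recording, out_dir)
    _write_ground_truth(truth, config, out_dir / "ground_truth.json")

    model = ThetaTravelingWave(
        recording, seed=_stage_seed(config.seed, 1)
    )
    results = model.fit()
    results.epochs.to_csv(out_dir / "epochs.csv")
    results.per_cycle.to_csv(out_dir / "cycles.csv", index=False)
    results.asymmetry.to_csv(out_dir / "asymmetry.csv", index=False)

    payload = results.to_json()
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    payload["provenance"] = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
    }
    (out_dir / "results.json").write_text(json.dumps(payload, indent=1))
    (out_dir / "summary.txt").write_text(results.summary() + "\n")
    return payload


def _write_ground_truth(truth: GroundTruth, config: SimConfig, path) -> None:
    fs_out = 100.0
    step = max(1, int(round(config.fs_hz / fs_out)))
    traj = truth.trajectory
    out = {
        "times_s": traj.times[::step],
        "phase_deg": traj.phase_deg[:, ::step],
        "freq_hz": traj.freq_hz[0, ::step],
        "asym_rd": truth.asym_rd,
        "asym_pt": truth.asym_pt,
        "locked": truth.locked,
        "artifact_times_s": truth.artifact_times_s,
    }
    Path(path).write_text(json.dumps(_to_jsonable(out)))
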