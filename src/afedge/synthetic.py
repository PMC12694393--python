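"""Seeded synthetic RR cohorts and ECG traces for download-free testing.

The generators emulate the one property the RR-based classifier exploits:
sinus rhythm is regular — slow respiratory (RSA) modulation plus small
beat-to-beat noise — while atrial fibrillation is irregularly irregular —
high-variance, weakly autocorrelated intervals.  Concretely:

* SR: ``RR_i = mean_rr + A sin(2 pi t_i / T) + eps_i`` with RSA amplitude
  ``A = 0.04`` s, period ``T = 4.5`` s, Gaussian noise sd 0.02 s and a
  per-subject mean RR drawn from U(0.7, 1.0) s.
* AF: i.i.d. Gamma intervals with per-subject mean from U(0.55, 0.85) s
  and coefficient of variation 0.22 (lag-1 autocorrelation ~ 0).

Both are clipped to [0.3, 1.8] s, strictly inside the [0.25, 2] s
plausibility filter, so the filter is a no-op on synthetic data and is
exercised by dedicated edge-case fixtures instead.  These are statistical
stand-ins, not physiological models; see docs/methods.md for what they do
and do not emulate.

A stereotyped synthetic ECG (Gaussian QRS-like deflections at the beat
times, 125 Hz) and a 12-bit DAC quantization model of the playback bench
complete the desk-scale test rig.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from afedge.ingest import Rhythm, RRSeries

ECG_FS_HZ = 125.0
CLIP_LO_S = 0.3
CLIP_HI_S = 1.8

SR_MEAN_RR_RANGE = (0.7, 1.0)
SR_NOISE_SD_S = 0.02
RSA_AMPLITUDE_S = 0.04
RSA_PERIOD_S = 4.5
AF_MEAN_RR_RANGE = (0.55, 0.85)
AF_CV = 0.22


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one synthetic subject under one rhythm."""

    subject_id: str
    rhythm: Rhythm
    mean_rr_s: float
    sr_noise_sd_s: float = SR_NOISE_SD_S
    rsa_amplitude_s: float = RSA_AMPLITUDE_S
    rsa_period_s: float = RSA_PERIOD_S
    af_cv: float = AF_CV
    n_beats: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.25 <= self.mean_rr_s <= 2.0:
            raise ValueError(f"mean RR {self.mean_rr_s} outside the plausible range")


@dataclass(frozen=True)
class SyntheticECG:
    """A synthetic trace in millivolts at 125 Hz plus its beat times."""

    samples: np.ndarray
    beat_times_s: np.ndarray
    sampling_rate_hz: float = ECG_FS_HZ


def gen_sr_rr(profile: SubjectProfile, n_beats: int | None = None) -> np.ndarray:
    """Sinus-rhythm RR series: RSA sinusoid plus Gaussian beat noise."""
    if profile.rhythm != Rhythm.SR:
        raise ValueError("profile rhythm must be SR")
    n = n_beats if n_beats is not None else profile.n_beats
    rng = np.random.default_rng(profile.seed)
    rr = np.empty(n)
    t = 0.0
    for i in range(n):
        v = (
            profile.mean_rr_s
            + profile.rsa_amplitude_s * np.sin(2.0 * np.pi * t / profile.rsa_period_s)
            + rng.normal(0.0, profile.sr_noise_sd_s)
        )
        rr[i] = v
        t += max(v, 1e-3)  # beat clock advances by the unclipped interval
    return np.clip(rr, CLIP_LO_S, CLIP_HI_S)


def gen_af_rr(profile: SubjectProfile, n_beats: int | None = None) -> np.ndarray:
    """AF RR series: i.i.d. Gamma intervals with the profile's mean and CV."""
    if profile.rhythm != Rhythm.AF:
        raise ValueError("profile rhythm must be AF")
    n = n_beats if n_beats is not None else profile.n_beats
    rng = np.random.default_rng(profile.seed)
    if profile.af_cv <= 0:
        return np.clip(np.full(n, profile.mean_rr_s), CLIP_LO_S, CLIP_HI_S)
    shape = 1.0 / profile.af_cv**2
    scale = profile.mean_rr_s / shape
    return np.clip(rng.gamma(shape, scale, size=n), CLIP_LO_S, CLIP_HI_S)


def gen_cohort(
    n_subjects: int = 23,
    af_fraction_of_time: float = 0.45,
    n_beats: int = 5000,
    seed: int = 0,
) -> tuple[dict[str, list[RRSeries]], dict]:
    """Generate a cohort of per-subject SR and AF RR series.

    Every subject carries both rhythms; beats are apportioned so that the
    subject's AF *time* fraction is drawn around ``af_fraction_of_time``
    (uniform ±0.2), keeping the cohort-level AF duration share near the
    requested value.  Returns the RR store (subject -> series list) and a
    manifest with every generative parameter.
    """
    if n_subjects < 15:
        raise ValueError("need at least 15 subjects to support 5 folds x 3 test subjects")
    rng = np.random.default_rng(seed)
    store: dict[str, list[RRSeries]] = {}
    manifest: dict = {
        "n_subjects": n_subjects,
        "af_fraction_of_time": af_fraction_of_time,
        "n_beats": n_beats,
        "seed": seed,
        "subjects": {},
    }
    for i in range(n_subjects):
        subject = f"syn{i + 1:03d}"
        sr_mean = rng.uniform(*SR_MEAN_RR_RANGE)
        af_mean = rng.uniform(*AF_MEAN_RR_RANGE)
        f_time = float(np.clip(rng.uniform(af_fraction_of_time - 0.2,
                                           af_fraction_of_time + 0.2), 0.05, 0.95))
        # n_af * af_mean / (n_af * af_mean + n_sr * sr_mean) = f_time
        n_af = int(round(n_beats / (1.0 + (af_mean / sr_mean) * (1.0 - f_time) / f_time)))
        n_af = min(max(n_af, 1), n_beats - 1)
        n_sr = n_beats - n_af
        sr_profile = SubjectProfile(
            subject, Rhythm.SR, sr_mean, n_beats=n_sr,
            seed=int(rng.integers(2**31)),
        )
        af_profile = SubjectProfile(
            subject, Rhythm.AF, af_mean, n_beats=n_af,
            seed=int(rng.integers(2**31)),
        )
        sr = RRSeries(subject, Rhythm.SR, gen_sr_rr(sr_profile))
        af = RRSeries(subject, Rhythm.AF, gen_af_rr(af_profile))
        store[subject] = [sr, af]
        manifest["subjects"][subject] = {
            "sr": asdict(sr_profile) | {"rhythm": "SR", "hours": sr.duration_s / 3600},
            "af": asdict(af_profile) | {"rhythm": "AF", "hours": af.duration_s / 3600},
        }
    total_af = sum(s[1].duration_s for s in store.values())
    total = sum(s[0].duration_s + s[1].duration_s for s in store.values())
    manifest["achieved_af_fraction_of_time"] = total_af / total
    return store, manifest


def gen_synthetic_ecg(rr_values: Sequence[float], fs_hz: float = ECG_FS_HZ) -> SyntheticECG:
    """Place a stereotyped QRS-like deflection at each beat time.

    The trace spans ``sum(rr)`` seconds.  Beat k sits at
    ``sum(rr[:k]) + rr[0]/2`` — the half-interval lead-in keeps every peak
    interior to the trace so a simple threshold detector recovers the beat
    count exactly.  Each beat is a 1 mV Gaussian of ~40 ms width on a
    0.05 mV respiratory-scale baseline wander.
    """
    rr = np.asarray(rr_values, dtype=float)
    if rr.size == 0:
        return SyntheticECG(np.empty(0), np.empty(0), fs_hz)
    if np.any((rr < 0.25) | (rr > 2.0)):
        raise ValueError("RR values must lie in [0.25, 2] s")
    duration = float(rr.sum())
    n_samples = int(np.ceil(duration * fs_hz - 1e-9))
    t = np.arange(n_samples) / fs_hz
    beat_times = np.concatenate([[0.0], np.cumsum(rr[:-1])]) + rr[0] / 2.0
    sigma = 0.017  # s; FWHM ~ 40 ms
    trace = 0.05 * np.sin(2.0 * np.pi * t / 5.0)  # slow baseline, 0.2 Hz
    for bt in beat_times:
        trace += 1.0 * np.exp(-0.5 * ((t - bt) / sigma) ** 2)
    return SyntheticECG(trace, beat_times, fs_hz)


def ecg_chunks_for_stream(
    rr_values: Sequence[float], fs_hz: float = ECG_FS_HZ
) -> list[np.ndarray]:
    """Split a synthetic trace into per-interval chunks for the simulator."""
    ecg = gen_synthetic_ecg(rr_values, fs_hz)
    edges = np.concatenate([[0.0], np.cumsum(np.asarray(rr_values, dtype=float))])
    idx = np.round(edges * fs_hz).astype(int)
    return [ecg.samples[idx[i] : idx[i + 1]] for i in range(len(rr_values))]


def quantize_to_dac(
    signal_mv: Sequence[float], vref_v: float = 3.3, bits: int = 12
) -> tuple[np.ndarray, float]:
    """Model the playback bench's DAC: uniform quantization over [0, vref].

    Returns the integer codes and the LSB size in millivolts
    (1000 * vref / 2**bits; 0.805 mV for a 3.3 V, 12-bit DAC).  The input
    is expected in millivolts already rescaled into [0, vref]; codes are
    floored and clipped to the code range, so the per-sample
    reconstruction error ``|code * lsb - signal|`` is at most one LSB.
    """
    if bits < 1:
        raise ValueError("bits must be >= 1")
    lsb_mv = 1000.0 * vref_v / 2**bits
    signal = np.asarray(signal_mv, dtype=float)
    codes = np.clip(np.floor(signal / lsb_mv), 0, 2**bits - 1).astype(int)
    return codes, lsb_mv


def write_cohort(
    store: dict[str, list[RRSeries]],
    manifest: dict,
    out_dir: str | Path,
    with_ecg: bool = False,
) -> None:
    """Write the cohort in the ingest module's per-subject CSV layout."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for subject, series_list in store.items():
        with open(out_dir / f"{subject}.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["rr_s", "rhythm"])
            for series in series_list:
                for v in series.values:
                    w.writerow([f"{v:.6f}", series.rhythm.value])
        if with_ecg:
            rr = series_list[0].values[:120]  # short illustrative trace
            ecg = gen_synthetic_ecg(rr)
            with open(out_dir / f"{subject}_ecg.csv", "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["ecg_mv"])
                for v in ecg.samples:
                    w.writerow([f"{v:.6f}"])
    with open(out_dir / "cohort_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_cohort(rr_dir: str | Path) -> dict[str, list[RRSeries]]:
    """Read a directory of per-subject RR CSVs back into an RR store."""
    from afedge.ingest import read_rr_csv

    store: dict[str, list[RRSeries]] = {}
    for path in sorted(Path(rr_dir).glob("*.csv")):
        if path.name.endswith("_ecg.csv"):
            continue
        store[path.stem] = read_rr_csv(path)
    return store
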