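"""Charge-integration (CI) acquisition channel.

Models the QDC branch: gated integration of the SiPM output charge at a
fixed repetition rate, additive electronic noise, pedestal offset, ADC
quantization, and non-overlapping block averaging.  Charge integration sees
no dead-time loss — overlapping single-photon pulses simply add charge — so
per gate the detected photoelectron count is Poisson with mean
``gate * (L(t) + dcr)`` and the charge is ``272 fC`` per photoelectron.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import substream
from .biolum_source import EmissionProfile
from .spc_channel import DetectorConfig

__all__ = [
    "QdcConfig",
    "ChargeTrace",
    "integrate_gates",
    "gates_from_pe",
    "block_average",
    "charge_to_photons",
    "photons_to_charge",
    "write_charge_trace",
    "read_charge_trace",
]


@dataclass(frozen=True)
class QdcConfig:
    """QDC branch configuration.

    ``gate`` is the integration gate (4–32 us valid), ``sampling_rate`` the
    gate repetition rate, ``block`` the averaging block size that restores
    the 2 Hz trace granularity used on lysates, ``charge_per_pe`` the
    single-photoelectron charge, ``pedestal`` the baseline offset in ADC
    channels, ``adc_gain`` the charge per ADC channel, and ``noise_sigma``
    the white Gaussian charge noise per gate contributed by the amplifier.
    ``drift_sigma`` optionally adds a slow baseline random walk (per-gate
    step amplitude) emulating residual baseline fluctuations; it is off by
    default.
    """

    gate: float = 5e-6
    charge_per_pe: float = 272e-15
    sampling_rate: float = 11.2e3
    block: int = 5600
    pedestal: float = 50.0
    adc_gain: float = 40e-15
    adc_bits: int = 12
    noise_sigma: float = 700e-15
    drift_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (4e-6 <= self.gate <= 32e-6):
            raise ValueError("gate must lie in [4 us, 32 us]")
        if not self.charge_per_pe > 0:
            raise ValueError("charge_per_pe must be > 0")
        if not self.block >= 1:
            raise ValueError("block must be >= 1")
        if not self.sampling_rate * self.gate <= 1.0:
            raise ValueError("sampling_rate * gate must not exceed 1 (duty cycle)")
        if not self.adc_gain > 0:
            raise ValueError("adc_gain must be > 0")
        if self.noise_sigma < 0 or self.drift_sigma < 0:
            raise ValueError("noise amplitudes must be >= 0")

    @property
    def pedestal_charge(self) -> float:
        """Pedestal offset expressed as charge (C)."""
        return self.pedestal * self.adc_gain

    @property
    def duty(self) -> float:
        """Fraction of real time covered by integration gates."""
        return self.sampling_rate * self.gate


@dataclass(frozen=True)
class ChargeTrace:
    """CI output: per-gate (or block-averaged) charge and derived quantities.

    ``charge`` is the ADC-reconstructed charge (C), ``pe_equiv`` its
    photoelectron equivalent above the pedestal, ``sample_dt`` the spacing
    between consecutive samples (1/sampling_rate raw, block/sampling_rate
    after averaging).
    """

    t: np.ndarray
    adc: np.ndarray
    charge: np.ndarray
    pe_equiv: np.ndarray
    saturated: np.ndarray
    gate: float
    sample_dt: float
    pedestal_charge: float
    charge_per_pe: float
    block: int = 1

    def __len__(self) -> int:
        return len(self.t)


def charge_to_photons(charge, qdc: QdcConfig):
    """Convert integrated charge to photoelectron equivalents.

    ``(charge - pedestal_charge) / charge_per_pe``; linear and invertible.
    """
    out = (np.asarray(charge, dtype=float) - qdc.pedestal_charge) / qdc.charge_per_pe
    return float(out) if out.ndim == 0 else out


def photons_to_charge(photons, qdc: QdcConfig):
    """Inverse of :func:`charge_to_photons`."""
    out = np.asarray(photons, dtype=float) * qdc.charge_per_pe + qdc.pedestal_charge
    return float(out) if out.ndim == 0 else out


def gates_from_pe(
    pe: np.ndarray,
    t: np.ndarray,
    qdc: QdcConfig,
    rng: np.random.Generator,
) -> ChargeTrace:
    """Turn per-gate photoelectron counts into a digitized charge trace.

    Adds white Gaussian charge noise, the optional random-walk drift, and
    the pedestal, then quantizes to ADC channels with clipping at the
    converter full scale (saturation flagged).
    """
    n = len(pe)
    charge_true = pe.astype(float) * qdc.charge_per_pe + qdc.pedestal_charge
    if qdc.noise_sigma > 0:
        charge_true = charge_true + rng.normal(0.0, qdc.noise_sigma, n)
    if qdc.drift_sigma > 0:
        charge_true = charge_true + np.cumsum(rng.normal(0.0, qdc.drift_sigma, n))
    adc_raw = np.rint(charge_true / qdc.adc_gain)
    full_scale = 2 ** qdc.adc_bits - 1
    # saturation means overflow; noise-driven underflow is clipped at channel
    # zero like in the hardware, where the pedestal exists to make it rare
    saturated = adc_raw > full_scale
    adc = np.clip(adc_raw, 0, full_scale)
    charge_meas = adc * qdc.adc_gain
    return ChargeTrace(
        t=t,
        adc=adc,
        charge=charge_meas,
        pe_equiv=charge_to_photons(charge_meas, qdc),
        saturated=saturated,
        gate=qdc.gate,
        sample_dt=1.0 / qdc.sampling_rate,
        pedestal_charge=qdc.pedestal_charge,
        charge_per_pe=qdc.charge_per_pe,
        block=1,
    )


def integrate_gates(
    profile: EmissionProfile,
    det: DetectorConfig,
    qdc: QdcConfig,
    rng: Optional[np.random.Generator] = None,
) -> ChargeTrace:
    """Simulate gated charge integration over the profile's time span.

    Per gate the photoelectron count is Poisson with mean
    ``gate * (L(t_gate) + dcr)``; no dead-time loss applies in this branch.
    Deterministic given the generator (or ``qdc.seed``).
    """
    if rng is None:
        rng = substream(qdc.seed, "ci.integrate_gates")
    fs = qdc.sampling_rate
    n_gates = int(math.floor(profile.duration * fs))
    if n_gates < 1:
        raise ValueError("profile shorter than one sampling interval")
    t = profile.t[0] + np.arange(n_gates) / fs
    rate = profile.rate_at(t) + det.dcr
    pe = rng.poisson(rate * qdc.gate)
    return gates_from_pe(pe, t, qdc, rng)


def block_average(trace: ChargeTrace, block: int) -> ChargeTrace:
    """Average a charge trace over non-overlapping blocks.

    Output rate is ``sampling_rate / block`` (e.g. 11.2 kHz / 5600 = 2 Hz);
    the trailing partial block is dropped.  A block saturates if any member
    gate saturated.
    """
    if not block >= 1:
        raise ValueError("block must be >= 1")
    n = len(trace)
    if block > n:
        raise ValueError(f"block ({block}) exceeds trace length ({n})")
    if block == 1:
        return trace
    n_out = n // block
    m = n_out * block

    def _mean(x: np.ndarray) -> np.ndarray:
        return x[:m].reshape(n_out, block).mean(axis=1)

    adc = _mean(trace.adc)
    charge = _mean(trace.charge)
    return ChargeTrace(
        t=trace.t[:m:block],
        adc=adc,
        charge=charge,
        pe_equiv=_mean(trace.pe_equiv),
        saturated=trace.saturated[:m].reshape(n_out, block).any(axis=1),
        gate=trace.gate,
        sample_dt=trace.sample_dt * block,
        pedestal_charge=trace.pedestal_charge,
        charge_per_pe=trace.charge_per_pe,
        block=trace.block * block,
    )


def write_charge_trace(trace: ChargeTrace, path) -> None:
    """Write the QDC trace table: (t_s, adc, charge_pC, pe_equiv, saturated)."""
    df = pd.DataFrame(
        {
            "t_s": trace.t,
            "adc": trace.adc,
            "charge_pC": trace.charge * 1e12,
            "pe_equiv": trace.pe_equiv,
            "saturated": trace.saturated.astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write(
            f"# CI charge trace: gate={trace.gate} s, sample_dt={trace.sample_dt} s, "
            f"block={trace.block}, pedestal_C={trace.pedestal_charge}, "
            f"charge_per_pe_C={trace.charge_per_pe}\n"
        )
        df.to_csv(fh, index=False)


def read_charge_trace(path, gate: float, sample_dt: float,
                      pedestal_charge: float, charge_per_pe: float,
                      block: int = 1) -> ChargeTrace:
    df = pd.read_csv(path, comment="#")
    return ChargeTrace(
        t=df["t_s"].to_numpy(),
        adc=df["adc"].to_numpy(dtype=float),
        charge=df["charge_pC"].to_numpy() * 1e-12,
        pe_equiv=df["pe_equiv"].to_numpy(),
        saturated=df["saturated"].to_numpy(dtype=bool),
        gate=gate,
        sample_dt=sample_dt,
        pedestal_charge=pedestal_charge,
        charge_per_pe=charge_per_pe,
        block=block,
    )
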