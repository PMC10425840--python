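"""Simulated sister-phased contact tables with closed-form ground truth.

Each simulated contact is an intra-chromosomal pair at genomic distance
``s`` drawn from a power-law density (the canonical Hi-C contact
frequency decay P(s) ~ s^-alpha), placed uniformly along a chromosome,
and phased cis (same chromatid) or trans (between sister chromatids)
with probability R(s) / (1 + R(s)) where

    R(s) = 1 + (R0 - 1) * exp(-s / lambda)

is the cis/trans ratio model: a short-range plateau R0 > 1 decaying to 1
(cis and trans equally likely) with decay length ``lambda``.  The
distance at which R(s) first reaches a threshold t is then available in
closed form,

    s* = lambda * ln((R0 - 1) / (t - 1)),

giving an exact oracle for the genomic resolution score recovered from
the simulated tables.  The exponential form is a convenient monotone
stand-in for empirical ratio curves, which decay from a plateau to 1
without a prescribed functional form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import CONTACT_COLUMNS, write_phased_pairs

__all__ = ["ContactModel", "TrueResolution", "ratio_model",
           "simulate_contacts", "true_resolution"]

DEFAULT_CHROM_SIZES = {"chr1": 200_000_000, "chr2": 150_000_000,
                       "chr3": 100_000_000}


@dataclass
class ContactModel:
    """Generative model of a sister-phased contact table.

    ``alpha`` is the contact-probability decay exponent, ``amplitude``
    the P(s) prefactor (bookkeeping only — sampled counts are set by
    ``n_contacts``), ``r0`` the short-range cis/trans plateau,
    ``lambda_mb`` the ratio decay length in Mb.
    """

    alpha: float = 1.0
    amplitude: float = 1.0
    r0: float = 2.0
    lambda_mb: float = 5.0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_SIZES))
    s_min: int = 1_000
    s_max: int = 100_000_000
    n_contacts: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r0 <= 1:
            raise ValueError("r0 must exceed 1")
        if self.lambda_mb <= 0 or self.alpha <= 0:
            raise ValueError("lambda_mb and alpha must be positive")
        if self.s_min < 1000:
            raise ValueError("s_min must be >= 1000 bp")
        if self.s_max <= self.s_min:
            raise ValueError("s_max must exceed s_min")
        if self.s_max > max(self.chrom_sizes.values()):
            raise ValueError("s_max exceeds the longest chromosome")


@dataclass
class TrueResolution:
    threshold: float
    s_star: float   # bp


def ratio_model(model: ContactModel, s) -> np.ndarray:
    """Cis/trans ratio R(s) = 1 + (R0 - 1) exp(-s / lambda) (s in bp)."""
    s = np.asarray(s, dtype=np.float64)
    lam = model.lambda_mb * 1e6
    return 1.0 + (model.r0 - 1.0) * np.exp(-s / lam)


def _sample_distances(model: ContactModel, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sampling from density ∝ s^-alpha on [s_min, s_max]."""
    u = rng.random(n)
    a, lo, hi = model.alpha, float(model.s_min), float(model.s_max)
    if np.isclose(a, 1.0):
        return lo * (hi / lo) ** u
    p = 1.0 - a
    return (lo**p + u * (hi**p - lo**p)) ** (1.0 / p)


def simulate_contacts(model: ContactModel,
                      pairs_path: str | Path | None = None,
                      truth_path: str | Path | None = None,
                      threshold: float = 1.25) -> pd.DataFrame:
    """Draw a phased contact table from the model; optionally write it.

    Distances come from the power-law density; each contact lands on a
    chromosome with probability proportional to the number of valid
    start positions (size - s), uniformly within it; the phase is a
    Bernoulli draw with cis probability R(s) / (1 + R(s)).  Distance and
    phase use independent sub-streams of the model seed, so the table is
    reproducible.
    """
    ss = np.random.SeedSequence(model.seed)
    rng_s, rng_chrom, rng_phase = (np.random.default_rng(c) for c in ss.spawn(3))

    s = np.floor(_sample_distances(model, model.n_contacts, rng_s)).astype(np.int64)
    names = list(model.chrom_sizes)
    sizes = np.array([model.chrom_sizes[c] for c in names], dtype=np.float64)
    room = np.maximum(sizes[None, :] - s[:, None], 0.0)   # valid starts per chrom
    weights = room / room.sum(axis=1, keepdims=True)
    cum = np.cumsum(weights, axis=1)
    pick = (rng_chrom.random(model.n_contacts)[:, None] < cum).argmax(axis=1)
    chrom_size = sizes[pick]
    pos1 = np.floor(rng_chrom.random(model.n_contacts) * (chrom_size - s)).astype(np.int64)
    pos2 = pos1 + s

    r = ratio_model(model, s)
    p_cis = r / (1.0 + r)
    is_cis = rng_phase.random(model.n_contacts) < p_cis
    table = pd.DataFrame({
        "chrom": np.array(names, dtype=object)[pick],
        "pos1": pos1,
        "pos2": pos2,
        "phase": np.where(is_cis, "cis", "trans"),
    })[CONTACT_COLUMNS]

    if pairs_path is not None:
        write_phased_pairs(table, pairs_path,
                           header_lines=[f"model: {model}"])
    if truth_path is not None:
        tr = true_resolution(model, threshold)
        Path(truth_path).write_text(json.dumps({
            "threshold": tr.threshold, "s_star_bp": tr.s_star,
            "r0": model.r0, "lambda_mb": model.lambda_mb,
            "alpha": model.alpha, "n_contacts": model.n_contacts,
            "seed": model.seed}, indent=2))
    return table


def true_resolution(model: ContactModel, threshold: float = 1.25) -> TrueResolution:
    """Closed-form distance where R(s) first reaches the threshold.

    s* = lambda · ln((R0 - 1) / (threshold - 1)); requires
    1 < threshold <= R0 (at threshold = R0 the plateau itself touches the
    threshold, s* = 0).
    """
    if not (1.0 < threshold <= model.r0):
        raise ValueError(
            f"threshold must lie in (1, r0={model.r0}], got {threshold}")
    lam = model.lambda_mb * 1e6
    s_star = lam * np.log((model.r0 - 1.0) / (threshold - 1.0))
    return TrueResolution(threshold=threshold, s_star=float(s_star))
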