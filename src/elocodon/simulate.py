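"""Synthetic coding sequences and expression tables with planted structure.

The generator emulates the statistical features the downstream analysis
relies on:

* per-gene variation in Elongator-targeted codon frequency — each gene
  draws a target-codon propensity ``theta_g ~ Beta(theta_alpha, theta_beta)``;
* clustering of target codons — interior codons follow a two-state Markov
  chain over {target, non-target} with stationary target frequency
  ``theta_g`` and a self-transition excess ``kappa``; ``kappa = 0`` gives
  independent codons, larger values give longer target runs (higher F_2,
  F_3, F_4; shorter D) at essentially unchanged F_T;
* a planted monotone dependence of expression change on codon load —
  ``LFC_g = beta * z_g + eps`` with ``z_g`` the standardized F_T and
  Gaussian noise ``eps ~ N(0, sigma_noise^2)``;
* a stylized significance model — a two-sided Gaussian test of
  ``LFC / se_lfc`` followed by Benjamini–Hochberg adjustment.

Randomness is split into named per-gene substreams derived from the master
seed, so enlarging ``n_genes`` extends a simulation without reshuffling
existing genes, and the same configuration always reproduces byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .codon_metrics import (
    GENETIC_CODE,
    TARGET_CODONS,
    compute_profiles_batch,
)
from .io import CodingSequence
from .stats import bh_adjust

__all__ = [
    "SimulationConfig",
    "simulate_cds_set",
    "simulate_expression",
    "simulate_two_organ_study",
    "TwoOrganStudy",
]

_TARGETS = sorted(TARGET_CODONS)
_NON_TARGETS = sorted(set(GENETIC_CODE) - TARGET_CODONS)

# substream labels of the seed-splitting scheme
_S_LENGTH, _S_THETA, _S_CODONS, _S_NOISE = 0, 1, 2, 3


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Lengths are in codons (start and stop included) and are drawn from a
    lognormal clipped to [50, 2000]; defaults approximate the length and
    target-codon-frequency spread of a plant coding transcriptome.
    ``beta_effect`` is the planted slope of LFC on standardized F_T, one
    value per organ (scalar for a one-organ study).
    """

    n_genes: int = 5000
    length_log_mean: float = 5.8   # median ~ 330 codons
    length_log_sd: float = 0.45
    theta_alpha: float = 12.0      # mean target propensity ~ 0.15
    theta_beta: float = 68.0
    kappa: float = 0.1
    beta_effect: float | tuple[float, ...] = -0.5
    sigma_noise: float = 0.5
    se_lfc: float = 0.25
    organs: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0 <= self.kappa < 1:
            raise ValueError(f"kappa must lie in [0, 1), got {self.kappa}")
        if min(self.theta_alpha, self.theta_beta) <= 0:
            raise ValueError("theta_alpha and theta_beta must be positive")
        if self.sigma_noise < 0 or self.se_lfc <= 0:
            raise ValueError("sigma_noise must be >= 0 and se_lfc > 0")

    def beta_for_organ(self, organ_index: int) -> float:
        if isinstance(self.beta_effect, (tuple, list)):
            if organ_index >= len(self.beta_effect):
                raise ValueError(
                    f"no beta_effect supplied for organ index {organ_index}"
                )
            return float(self.beta_effect[organ_index])
        return float(self.beta_effect)


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def _gene_length(config: SimulationConfig, g: int) -> int:
    rng = _rng(config, _S_LENGTH, g)
    n = rng.lognormal(config.length_log_mean, config.length_log_sd)
    return int(np.clip(round(n), 50, 2000))


def _gene_theta(config: SimulationConfig, g: int) -> float:
    rng = _rng(config, _S_THETA, g)
    return float(rng.beta(config.theta_alpha, config.theta_beta))


def _interior_codons(config: SimulationConfig, g: int, n: int, theta: float) -> list[str]:
    """Two-state Markov chain over {target, non-target}, stationary at theta."""
    p_tt = theta + config.kappa * (1.0 - theta)
    p_nt = theta * (1.0 - p_tt) / (1.0 - theta)  # preserves stationarity
    if not (0.0 <= p_tt <= 1.0 and 0.0 <= p_nt <= 1.0):
        raise ValueError(
            f"gene {g}: transition probability outside [0, 1] "
            f"(theta={theta:.4f}, kappa={config.kappa})"
        )
    rng = _rng(config, _S_CODONS, g)
    u = rng.random(n)
    states = np.empty(n, dtype=bool)
    prev = u[0] < theta  # first interior codon from the stationary law
    states[0] = prev
    for i in range(1, n):
        prev = u[i] < (p_tt if prev else p_nt)
        states[i] = prev
    idx_t = rng.integers(0, len(_TARGETS), size=n)
    idx_n = rng.integers(0, len(_NON_TARGETS), size=n)
    return [
        _TARGETS[idx_t[i]] if states[i] else _NON_TARGETS[idx_n[i]]
        for i in range(n)
    ]


def simulate_cds_set(config: SimulationConfig) -> list[CodingSequence]:
    """Generate ``n_genes`` in-frame coding sequences (ATG ... TAA)."""
    records = []
    for g in range(config.n_genes):
        length = _gene_length(config, g)
        theta = _gene_theta(config, g)
        interior = _interior_codons(config, g, length - 2, theta)
        seq = "ATG" + "".join(interior) + "TAA"
        records.append(CodingSequence(f"g{g:05d}", seq))
    return records


def simulate_expression(
    profiles: pd.DataFrame,
    config: SimulationConfig,
    organ_index: int = 0,
) -> pd.DataFrame:
    """Expression table with a planted LFC ~ codon-load dependence.

    ``lfc = beta * z + eps`` with ``z`` the standardized F_T over the
    profile set; ``base_mean ~ LogNormal(5, 1)``; the p-value is a
    two-sided Gaussian test of ``lfc / se_lfc`` and padj its BH adjustment.
    """
    ft = profiles["F_T"].to_numpy(dtype=float)
    if np.ptp(ft) == 0:
        raise ValueError("degenerate profile set: F_T has zero variance")
    sd = ft.std(ddof=0)
    z = (ft - ft.mean()) / sd
    beta = config.beta_for_organ(organ_index)
    rng = _rng(config, _S_NOISE, organ_index)
    eps = rng.normal(0.0, config.sigma_noise, size=len(z))
    lfc = beta * z + eps
    base_mean = rng.lognormal(5.0, 1.0, size=len(z))
    pvalue = 2.0 * sps.norm.sf(np.abs(lfc) / config.se_lfc)
    return pd.DataFrame({
        "gene_id": profiles["gene_id"].to_numpy(),
        "base_mean": base_mean,
        "lfc": lfc,
        "pvalue": pvalue,
        "padj": bh_adjust(pvalue),
    })


class TwoOrganStudy(NamedTuple):
    cds: list[CodingSequence]
    profiles: pd.DataFrame
    hypocotyl: pd.DataFrame
    cotyledon: pd.DataFrame


def simulate_two_organ_study(config: SimulationConfig) -> TwoOrganStudy:
    """One shared CDS set with independent expression tables per organ.

    Organ index 0 is the hypocotyl, index 1 the cotyledon; the two noise
    streams are split deterministically from the master seed.
    """
    if config.organs != 2:
        raise ValueError("simulate_two_organ_study requires organs=2")
    if not isinstance(config.beta_effect, (tuple, list)) or len(config.beta_effect) < 2:
        raise ValueError("two beta_effect values required for a two-organ study")
    cds = simulate_cds_set(config)
    profiles = compute_profiles_batch(cds)
    hyp = simulate_expression(profiles, config, organ_index=0)
    cot = simulate_expression(profiles, config, organ_index=1)
    hyp["organ"] = "hypocotyl"
    cot["organ"] = "cotyledon"
    return TwoOrganStudy(cds, profiles, hyp, cot)


def null_config(config: SimulationConfig) -> SimulationConfig:
    """The same study conditions with the planted effect removed."""
    beta = (0.0,) * config.organs if config.organs > 1 else 0.0
    return replace(config, beta_effect=beta)
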