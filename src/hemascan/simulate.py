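"""Synthetic cohort generator with known ground truth.

Produces every input the downstream pipeline consumes:

* genotypes with LD-block structure under Hardy-Weinberg equilibrium
  (a latent AR(1) Gaussian per haplotype, thresholded at the allele
  frequency quantile);
* per-donor, per-condition cytometry event clouds drawn from
  gate-anchored Gaussian mixtures in (FSC, SSC, SFL) space, where donor
  latent traits (e.g. the evoked NE2 neutrophil fraction) shift gate
  weights through genotype, disease status and noise;
* EHR-style clinical outcomes with delayed entry, problem-list events
  without dates, and administrative censoring, plus continuous labs.

Everything is driven by one :class:`~hemascan.config.SimulationConfig`
and a single seed; identical seeds reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import CHANNELS, INSTRUMENT_MAX, SimulationConfig
from .gating import EventTable
from .genotypes import GenotypeMatrix


def _rng(config_seed: int, stream: str) -> np.random.Generator:
    """Independent child stream derived from the config seed and a label."""
    import hashlib

    h = hashlib.blake2b(f"{config_seed}:{stream}".encode(), digest_size=8)
    return np.random.default_rng(int.from_bytes(h.digest(), "big") % (2**31))


# ---------------------------------------------------------------------------
# Genotypes


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """LD-structured diploid genotypes under HWE.

    Each haplotype is a latent Gaussian AR(1) chain within LD blocks
    (correlation ``ld_rho`` between adjacent variants, blocks independent),
    thresholded at the standard-normal quantile of the alt-allele
    frequency, so marginal frequencies match the configured MAF draw and
    adjacent-variant correlation rises with ``ld_rho``.
    """
    rng = _rng(config.seed, "genotypes")
    n, m = config.n_donors, config.n_variants
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)
    thresh = stats.norm.ppf(1.0 - maf)  # alt allele is the minor allele

    def haplotypes() -> np.ndarray:
        z = np.empty((n, m))
        for start in range(0, m, config.ld_block_size):
            stop = min(start + config.ld_block_size, m)
            eps = rng.standard_normal((n, stop - start))
            z[:, start] = eps[:, 0]
            for j in range(1, stop - start):
                z[:, start + j] = (
                    config.ld_rho * z[:, start + j - 1]
                    + np.sqrt(1 - config.ld_rho**2) * eps[:, j]
                )
        return (z > thresh).astype(float)

    dosages = haplotypes() + haplotypes()
    if config.genotype_missing_rate > 0:
        mask = rng.random((n, m)) < config.genotype_missing_rate
        dosages[mask] = np.nan

    gaps = rng.integers(1000, 9000, size=m)
    pos = np.cumsum(gaps)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "id": [f"var{j}" for j in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )
    donors = [f"D{i:05d}" for i in range(n)]
    gm = GenotypeMatrix(dosages=dosages, donors=donors, variants=variants)
    gm.recompute_summaries()
    return gm


# ---------------------------------------------------------------------------
# Donor latent state


@dataclass
class DonorState:
    """Latent per-donor quantities that drive events and outcomes."""

    donor: str
    disease: int
    tone: float  # inflammatory tone (s.d. units)
    #: per (condition, gate) log-scale weight shift
    weight_shift: dict[tuple[str, str], float]
    #: named latent traits exposed to the outcome simulator
    latents: dict[str, float]


def simulate_donor_states(
    config: SimulationConfig, genotypes: GenotypeMatrix
) -> list[DonorState]:
    """Latent gate-weight shifts per donor.

    Every causal effect adds ``effect_size x standardized dosage`` to the
    log-weight of its target (condition, gate); the donor's inflammatory
    tone (a standard-normal latent shifted by disease status) loads on all
    evoked gates; independent Gaussian noise with s.d. ``latent_noise_sd``
    completes the latent trait.
    """
    rng = _rng(config.seed, "donor_states")
    n = config.n_donors
    disease = (rng.random(n) < config.disease_prevalence).astype(int)
    tone = rng.standard_normal(n) + config.tone_disease_shift * disease

    dos = np.nan_to_num(genotypes.dosages, nan=0.0)
    freq = genotypes.allele_frequencies()
    sd = np.sqrt(np.maximum(2 * freq * (1 - freq), 1e-12))
    g_std = (dos - 2 * freq) / sd

    # noise per donor per causal target, plus per evoked gate via tone only
    targets = sorted({(c.condition, c.gate) for c in config.causal_effects})
    noise = {t: rng.standard_normal(n) * config.latent_noise_sd for t in targets}

    states = []
    for i, donor in enumerate(genotypes.donors):
        shift: dict[tuple[str, str], float] = {}
        latents: dict[str, float] = {"tone": float(tone[i])}
        for t in targets:
            shift[t] = float(noise[t][i])
        for eff in config.causal_effects:
            key = (eff.condition, eff.gate)
            shift[key] += eff.effect_size * float(g_std[i, eff.variant])
        for key, val in shift.items():
            latents[f"{key[1]}_{key[0]}"] = val
        # tone loads on every evoked (non-baseline) gate
        for gate in config.gate_templates:
            for cond in config.conditions:
                if cond == "baseline":
                    continue
                base_w = gate.weights.get(cond, 0.0)
                if base_w > 0 and gate.weights.get("baseline", 0.0) < base_w:
                    key = (cond, gate.name)
                    shift[key] = shift.get(key, 0.0) + config.tone_loading * tone[i]
        states.append(
            DonorState(
                donor=donor,
                disease=int(disease[i]),
                tone=float(tone[i]),
                weight_shift=shift,
                latents=latents,
            )
        )
    return states


# ---------------------------------------------------------------------------
# Events


def adjusted_weights(
    config: SimulationConfig, state: DonorState, condition: str, channel: str
) -> tuple[list[str], np.ndarray]:
    """Gate weights for one donor/condition/channel after latent modulation.

    Log-scale shifts multiply baseline weights; negative adjusted weights
    cannot arise on this scale, but explicit zero-clipping guards any
    additive extension.  Weights renormalize to 1; an all-zero vector is
    an error.
    """
    gates = [g for g in config.gate_templates if g.channel == channel]
    names = [g.name for g in gates]
    w = np.array([g.weights.get(condition, 0.0) for g in gates], dtype=float)
    for k, g in enumerate(gates):
        shift = state.weight_shift.get((condition, g.name))
        if shift is not None and w[k] > 0:
            w[k] = w[k] * np.exp(shift)
    w = np.clip(w, 0.0, None)
    tot = w.sum()
    if tot <= 0:
        raise ValueError(
            f"all gate weights zero for ({condition}, {channel}); cannot sample"
        )
    return names, w / tot


def simulate_events(
    state: DonorState, condition: str, config: SimulationConfig
) -> list[EventTable]:
    """Event clouds (one table per channel) for one donor under one condition."""
    rng = _rng(config.seed, f"events:{state.donor}:{condition}")
    tables = []
    for channel in CHANNELS:
        gates = [g for g in config.gate_templates if g.channel == channel]
        if not gates:
            continue
        names, w = adjusted_weights(config, state, condition, channel)
        counts = rng.multinomial(config.events_per_sample, w)
        chunks = []
        for g, c in zip(gates, counts):
            if c == 0:
                continue
            pts = rng.standard_normal((c, 3)) * np.asarray(g.spread) + np.asarray(
                g.mean
            )
            chunks.append(pts)
        events = np.vstack(chunks) if chunks else np.empty((0, 3))
        events = np.clip(events, 0.0, INSTRUMENT_MAX - 1e-9)
        tables.append(EventTable(state.donor, condition, channel, events))
    return tables


def simulate_cohort_events(
    config: SimulationConfig, states: list[DonorState]
) -> list[EventTable]:
    tables = []
    for state in states:
        for condition in config.conditions:
            tables.extend(simulate_events(state, condition, config))
    return tables


# ---------------------------------------------------------------------------
# Covariates and outcomes


def simulate_covariates(config: SimulationConfig, states: list[DonorState]) -> pd.DataFrame:
    """Donor covariates and continuous labs.

    eGFR declines with age and inflammatory tone; HbA1C rises with disease
    status.  Lab population means come from the config.
    """
    rng = _rng(config.seed, "covariates")
    n = len(states)
    age = rng.uniform(30, 75, size=n)
    sex = rng.integers(0, 2, size=n)
    race = rng.choice(["A", "B", "C"], size=n, p=[0.7, 0.2, 0.1])
    draw_time = rng.uniform(0.5, 36.0, size=n)  # hours from draw to analysis
    tone = np.array([s.tone for s in states])
    disease = np.array([s.disease for s in states])
    egfr = (
        config.lab_means.get("eGFR", 90.0)
        - 0.5 * (age - 50)
        - 4.0 * tone
        + rng.standard_normal(n) * 8.0
    )
    hba1c = (
        config.lab_means.get("HbA1C", 5.6)
        + 0.6 * disease
        + rng.standard_normal(n) * 0.5
    )
    return pd.DataFrame(
        {
            "donor": [s.donor for s in states],
            "age": age,
            "sex": sex,
            "race": race,
            "draw_time": draw_time,
            "disease": disease,
            "eGFR": np.maximum(egfr, 5.0),
            "HbA1C": np.maximum(hba1c, 4.0),
        }
    )


def simulate_outcomes(
    donor_latents: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """EHR-style outcome records with delayed entry.

    True onset ages follow a Weibull proportional-hazards model,
    ``S(t) = exp(-(t/scale)^shape x exp(sum log_hr x latent))``, whose
    age-increasing baseline hazard (shape > 1) concentrates onsets late in
    life as for chronic disease; donors enter observation
    at a first-visit age independent of onset.  Records expose only entry
    age, an observed diagnosis age (or none), a censoring age and a
    problem-list-only flag: onsets before entry surface either as undated
    problem-list diagnoses or as diagnoses recorded shortly after entry,
    exercising the downstream instant-event encoding.
    """
    rng = _rng(config.seed, "outcomes")
    donors = donor_latents.index.to_list()
    n = len(donors)
    latent_cols = {c: donor_latents[c].to_numpy(dtype=float) for c in donor_latents.columns}

    rows = []
    for outcome in config.outcomes:
        lp = np.zeros(n)
        for eff in config.outcome_effects:
            if eff.outcome != outcome:
                continue
            if eff.latent not in latent_cols:
                raise ValueError(
                    f"outcome effect references unknown latent {eff.latent!r}"
                )
            lp += eff.log_hr * latent_cols[eff.latent]
        # inverse-transform Weibull PH draw: t = scale * (E / exp(lp))^(1/shape)
        e = rng.exponential(1.0, size=n)
        onset = config.onset_scale * (e / np.exp(lp)) ** (1.0 / config.onset_shape)
        entry = rng.uniform(30, 60, size=n)
        censor = entry + rng.uniform(5, 25, size=n)
        problem_list = rng.random(n) < 0.3
        for i, donor in enumerate(donors):
            dx_age = np.nan
            plist = False
            if onset[i] <= entry[i]:
                # prevalent case: either undated problem-list entry or a
                # diagnosis recorded shortly after the first visit
                if problem_list[i]:
                    plist = True
                else:
                    dx_age = entry[i] + rng.uniform(0.0, 0.9)
            elif onset[i] <= censor[i]:
                dx_age = onset[i]
            rows.append(
                {
                    "donor": donor,
                    "outcome": outcome,
                    "entry_age": entry[i],
                    "diagnosis_age": dx_age,
                    "censor_age": censor[i],
                    "problem_list_only": plist,
                    "true_onset_age": onset[i],
                }
            )
    return pd.DataFrame(rows)


def latent_frame(states: list[DonorState]) -> pd.DataFrame:
    """Donor x latent-trait matrix for the outcome simulator."""
    df = pd.DataFrame([s.latents for s in states], index=[s.donor for s in states])
    return df.fillna(0.0)
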