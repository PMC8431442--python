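"""Synthetic blood small-EV miRNA cohorts with planted diagnostic structure.

The generator emulates the study design the pipeline targets: a PDAC group
and a chronic-pancreatitis (CP) group (optionally healthy controls),
negative-binomial read counts with specimen-level library-size variation,
a guaranteed housekeeping pool, one planted miRNA up-regulated in PDAC and
one up-regulated in CP (the diagnostic ratio pair), a planted
metastasis-associated pair inside the PDAC group, log-normal serum CA19-9
and CEA levels, and exponential overall survival whose hazard is tied to
the metastasis ratio marker.

The negative binomial is parameterized by mean mu and dispersion phi with
variance mu + phi * mu^2 (the standard RNA-seq count model).  One global
seed drives three independent sub-streams (counts, clinical, survival) via
numpy's SeedSequence spawning, so each component is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

__all__ = ["SimConfig", "SimulatedCohort", "simulate_cohort", "simulate_survival",
           "analytic_ratio_auc", "planted_ratio_params"]

# ids of the planted markers, named after the miRNAs whose roles they emulate
DIAG_UP = "miR-95-3p"      # up in PDAC (ratio numerator)
DIAG_DOWN = "miR-26b-5p"   # up in CP (ratio denominator)
MET_UP = "miR-335-5p"      # up in metastatic (M1) PDAC
MET_DOWN = "miR-340-5p"    # up in non-metastatic (M0) PDAC


@dataclass
class SimConfig:
    """Cohort-generator settings.

    Group sizes default to the training cohort (30 PDAC, 18 CP); 40% of PDAC
    specimens are metastatic (12/30).  CA19-9 moments for PDAC come from the
    cohort table (560.7 +- 496.7 U/ml); the CP distribution is set to a
    typical benign range (24 +- 15 U/ml).  Baselines are log-uniform over
    10^baseline_log10_range reads; planted markers sit at high abundance
    (25x the top of the range) so they clear the mean>=50 abundance filter
    the way the real candidates do.
    """

    n_pdac: int = 30
    n_cp: int = 18
    n_healthy: int = 0
    n_mirna: int = 334
    frac_metastatic: float = 0.4
    baseline_log10_range: tuple[float, float] = (0.0, 4.0)
    libsize_sigma: float = 0.25
    dispersion: float = 0.1
    diag_log2fc: float = 2.0
    met_log2fc: float = 1.5
    ca199_pdac_mean: float = 560.7
    ca199_pdac_sd: float = 496.7
    ca199_cp_mean: float = 24.0
    ca199_cp_sd: float = 15.0
    cea_pdac_mean: float = 5.5
    cea_pdac_sd: float = 4.0
    cea_cp_mean: float = 2.5
    cea_cp_sd: float = 1.5
    # calibrated so a specimen sitting at the metastatic-ratio cutoff (0.15)
    # has a median survival of ~413 days under the default log-hazard slope
    surv_base_hazard: float = np.log(2) / 413.0 / 0.15
    surv_log_hr: float = 1.0                     # per unit log(marker)
    censor_max: float = 1500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pdac, self.n_cp, self.n_healthy, self.n_mirna) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_mirna < 10:
            raise ValueError("n_mirna must be >= 10 to plant 4 markers plus housekeeping")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0.0 <= self.frac_metastatic <= 1.0:
            raise ValueError("frac_metastatic must be in [0,1]")
        if self.libsize_sigma < 0:
            raise ValueError("libsize_sigma must be >= 0")
        if self.surv_base_hazard <= 0:
            raise ValueError("surv_base_hazard must be positive")

    def streams(self) -> dict[str, np.random.Generator]:
        """The documented stream-splitting scheme: one child stream each for
        counts, clinical covariates and survival."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        names = ("counts", "clinical", "survival")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class SimulatedCohort:
    counts: pd.DataFrame
    samples: pd.DataFrame
    truth: dict = field(repr=False)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, phi) with variance mu + phi mu^2, via numpy's (n, p) form."""
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given arithmetic mean and SD."""
    v = sd**2
    sigma2 = np.log(1.0 + v / mean**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Draw a full cohort: counts, clinical table and planted-truth map.

    counts[m, j] ~ NB(a_m * s_j * 2^effect(m, group j), dispersion) with
    a_m log-uniform over the baseline range and s_j log-normal(0,
    libsize_sigma).  The planted diagnostic pair receives +diag_log2fc in
    PDAC (numerator) and +diag_log2fc in CP (denominator); the planted
    metastasis pair receives +met_log2fc in M1 and M0 PDAC respectively.
    The top-abundance decile is floored at 1 read per specimen so a
    housekeeping pool always exists.  Deterministic given config.seed.
    """
    if config.n_pdac < 1 or config.n_cp < 1:
        raise ValueError("diagnostic analysis needs both PDAC and CP specimens")
    streams = config.streams()
    rng_c, rng_k = streams["counts"], streams["clinical"]

    n_spec = config.n_pdac + config.n_cp + config.n_healthy
    specimen_ids = (
        [f"PDAC-{i + 1:03d}" for i in range(config.n_pdac)]
        + [f"CP-{i + 1:03d}" for i in range(config.n_cp)]
        + [f"HC-{i + 1:03d}" for i in range(config.n_healthy)]
    )
    diagnosis = np.array(
        ["PDAC"] * config.n_pdac + ["CP"] * config.n_cp + ["healthy"] * config.n_healthy
    )

    lo, hi = config.baseline_log10_range
    n_free = config.n_mirna - 4
    mirna_ids = [DIAG_UP, DIAG_DOWN, MET_UP, MET_DOWN] + [
        f"miR-sim-{i + 1:04d}" for i in range(n_free)
    ]
    baselines = np.empty(config.n_mirna)
    planted_baseline = 25.0 * 10.0**hi
    # denominator baselines are scaled so the group-geometric-center of each
    # planted ratio sits at the scale of its decision cutoff (~0.06 diagnostic,
    # 0.15 metastatic), as for the markers the pipeline emulates
    baselines[0] = planted_baseline                 # diag numerator
    baselines[1] = planted_baseline / 0.0625        # diag denominator
    baselines[2] = planted_baseline                 # met numerator
    baselines[3] = planted_baseline / 0.15          # met denominator
    baselines[4:] = 10.0 ** rng_c.uniform(lo, hi, size=n_free)

    # metastasis labels (clinical stream, before counts so the met effect is known)
    n_m1 = int(round(config.frac_metastatic * config.n_pdac))
    m1_idx = rng_k.choice(config.n_pdac, size=n_m1, replace=False)
    metastasis = np.array([None] * n_spec, dtype=object)
    metastasis[: config.n_pdac] = "M0"
    metastasis[m1_idx] = "M1"

    # log2 effect matrix (miRNA x specimen), nonzero only for planted rows
    effects = np.zeros((config.n_mirna, n_spec))
    is_pdac = diagnosis == "PDAC"
    is_cp = diagnosis == "CP"
    is_m1 = metastasis == "M1"
    is_m0 = metastasis == "M0"
    effects[0, is_pdac] = config.diag_log2fc
    effects[1, is_cp] = config.diag_log2fc
    effects[2, is_m1] = config.met_log2fc
    effects[3, is_m0] = config.met_log2fc

    libsize = np.exp(rng_c.normal(0.0, config.libsize_sigma, size=n_spec))
    mean = baselines[:, None] * libsize[None, :] * 2.0**effects
    counts = _nb_draw(rng_c, mean, config.dispersion)

    # guaranteed housekeeping pool: floor the top-abundance decile at 1 read
    n_top = max(1, config.n_mirna // 10)
    top_idx = np.argsort(baselines)[::-1][:n_top]
    counts[top_idx] = np.maximum(counts[top_idx], 1)

    counts_df = pd.DataFrame(counts, index=mirna_ids, columns=specimen_ids)

    ca199 = np.full(n_spec, np.nan)
    cea = np.full(n_spec, np.nan)
    for mask, (cm, cs), (em, es) in (
        (is_pdac, (config.ca199_pdac_mean, config.ca199_pdac_sd),
         (config.cea_pdac_mean, config.cea_pdac_sd)),
        (~is_pdac, (config.ca199_cp_mean, config.ca199_cp_sd),
         (config.cea_cp_mean, config.cea_cp_sd)),
    ):
        k = int(mask.sum())
        if k:
            mu, sg = _lognormal_params(cm, cs)
            ca199[mask] = rng_k.lognormal(mu, sg, size=k)
            mu, sg = _lognormal_params(em, es)
            cea[mask] = rng_k.lognormal(mu, sg, size=k)

    samples = pd.DataFrame(
        {
            "diagnosis": diagnosis,
            "metastasis": metastasis,
            "ca199_u_ml": ca199,
            "cea_ng_ml": cea,
            "os_days": np.nan,
            "os_event": pd.array([pd.NA] * n_spec, dtype="boolean"),
        },
        index=pd.Index(specimen_ids, name="specimen_id"),
    )

    true_log2fc = pd.Series(0.0, index=mirna_ids)
    true_log2fc[DIAG_UP] = config.diag_log2fc
    true_log2fc[DIAG_DOWN] = -config.diag_log2fc
    truth = {
        "diag_up_mirna": DIAG_UP,
        "diag_down_mirna": DIAG_DOWN,
        "met_up_mirna": MET_UP,
        "met_down_mirna": MET_DOWN,
        "true_log2fc": true_log2fc.to_dict() if config.diag_log2fc else
                       {m: 0.0 for m in mirna_ids},
        "housekeeping_guaranteed": [mirna_ids[i] for i in sorted(top_idx)],
        "planted_baseline": planted_baseline,
    }
    return SimulatedCohort(counts=counts_df, samples=samples, truth=truth)


def simulate_survival(samples: pd.DataFrame, marker: pd.Series,
                      config: SimConfig) -> pd.DataFrame:
    """Attach exponential overall survival to the PDAC specimens.

    Hazard = surv_base_hazard * exp(surv_log_hr * log(marker)); censoring is
    uniform on (0, censor_max]; os_days = min(event time, censoring time)
    and os_event flags an observed death.  Deterministic given config.seed
    (the dedicated survival stream).
    """
    rng = config.streams()["survival"]
    out = samples.copy()
    pdac = out.index[out["diagnosis"] == "PDAC"]
    missing = [s for s in pdac if s not in marker.index or not np.isfinite(marker[s])]
    if missing:
        raise ValueError(f"marker undefined for PDAC specimens: {missing[:3]}")
    m = marker.loc[pdac].to_numpy(dtype=float)
    if (m <= 0).any():
        raise ValueError("marker must be positive (its log enters the hazard)")
    hazard = config.surv_base_hazard * np.exp(config.surv_log_hr * np.log(m))
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, config.censor_max, size=len(pdac))
    censor_time = np.maximum(censor_time, np.finfo(float).tiny)
    os_days = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    out.loc[pdac, "os_days"] = os_days
    out["os_event"] = out["os_event"].astype("boolean")
    out.loc[pdac, "os_event"] = event
    return out


def analytic_ratio_auc(delta_log: float, sigma_log: float) -> float:
    """Exact AUC of a log-normal ratio marker.

    When the log-ratio is normal in both groups with common SD sigma_log and
    group mean difference delta_log, the AUC is Phi(delta_log /
    (sigma_log * sqrt(2))).
    """
    if sigma_log <= 0:
        raise ValueError("sigma_log must be positive")
    return float(_norm.cdf(delta_log / (sigma_log * np.sqrt(2.0))))


def planted_ratio_params(config: SimConfig) -> tuple[float, float]:
    """Delta-method log-scale parameters of the planted diagnostic ratio.

    The numerator gains +diag_log2fc in PDAC and the denominator +diag_log2fc
    in CP, so the group difference of the log-ratio is 2 * diag_log2fc * ln 2.
    Var(log NB(mu, phi)) ~ phi + 1/mu per component; library size cancels in
    the quotient.
    """
    delta = 2.0 * config.diag_log2fc * np.log(2.0)
    mu = 25.0 * 10.0 ** config.baseline_log10_range[1]
    var = 2.0 * (config.dispersion + 1.0 / mu)
    return delta, float(np.sqrt(var))
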