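"""Synthetic equilibrium-dialysis screens with known ground truth.

The generator emulates the statistical structure of a pooled FIA-MS
dialysis screen so every scoring stage can be exercised without external
data:

* per-metabolite baseline abundances drawn log-normally across ~3 decades
  of FIA-MS dynamic range;
* triplicate dialysis x triplicate injection AUCs with log2-scale
  replicate and technical noise;
* a low-rank latent structure (default 3 components at ~75% of
  fold-change variance) injected on the protein chamber only, so it
  contaminates fold changes exactly as shared batch/carry-over variation
  would;
* spiked depletion (substrate consumption, negative delta) and enrichment
  (binding, positive delta) effects on chosen pairs;
* rare gross outliers (default rate 0.1%) multiplying a random injection's
  AUC by ``2**outlier_magnitude``.

Everything is driven by one seed; the same seed and config give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import MeasurementTable, MetaboliteEntry, MetaboliteLibrary

__all__ = [
    "SpikeSpec",
    "GeneratorConfig",
    "SyntheticTruth",
    "Scenario",
    "make_library",
    "generate_screen",
    "preset_dhtkd1_like",
    "DHTKD1_REPORTED",
    "dhtkd1_reported_interactions",
    "synthetic_s1_standin",
]


@dataclasses.dataclass(frozen=True)
class SpikeSpec:
    """A ground-truth effect on one pair, applied in the protein chamber.

    ``delta`` is the true log2 fold change: negative = consumption
    (depletion from the protein chamber), positive = binding (enrichment).
    """

    protein_id: str
    metabolite_id: str
    delta: float

    def __post_init__(self):
        if not np.isfinite(self.delta):
            raise ValueError("spike delta must be finite")


@dataclasses.dataclass
class GeneratorConfig:
    """Study conditions for one synthetic screen.

    Defaults mirror the reference screen design: 412 metabolites in 4
    pools, triplicate dialysis x triplicate injection, a 3-component
    latent structure carrying ~75% of fold-change variance, and a 0.1%
    gross-outlier rate.  Noise SDs are in log2 units (0.2 ~ 15% CV,
    typical of flow-injection MS).
    """

    n_proteins: int = 60
    n_metabolites: int = 412
    n_pools: int = 4
    n_dialysis_reps: int = 3
    n_tech_reps: int = 3
    k_latent: int = 3
    latent_variance_target: float = 0.75
    replicate_noise_sd: float = 0.2
    tech_noise_sd: float = 0.2
    outlier_rate: float = 0.001
    outlier_magnitude: float = 6.0
    baseline_log10_range: tuple = (4.0, 7.0)
    seed: int = 0

    def __post_init__(self):
        for f in (
            "n_proteins",
            "n_metabolites",
            "n_pools",
            "n_dialysis_reps",
            "n_tech_reps",
        ):
            if int(getattr(self, f)) < 1:
                raise ValueError(f"{f} must be >= 1")
        if self.k_latent < 0:
            raise ValueError("k_latent must be >= 0")
        if self.k_latent > 0 and not (0 <= self.latent_variance_target < 1):
            raise ValueError("latent_variance_target must be in [0, 1)")
        for f in ("replicate_noise_sd", "tech_noise_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if not (0 <= self.outlier_rate < 1):
            raise ValueError("outlier_rate must be in [0, 1)")


@dataclasses.dataclass
class SyntheticTruth:
    """Everything the generator decided: spikes, latent structure, outliers."""

    spikes: list
    latent_scores: np.ndarray  # proteins x k
    latent_loadings: np.ndarray  # k x metabolites
    latent_scale: float
    outlier_positions: pd.DataFrame
    seed: int
    config: GeneratorConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "latent_scale": self.latent_scale,
            "spikes": [dataclasses.asdict(s) for s in self.spikes],
            "outliers": self.outlier_positions.to_dict(orient="records"),
            "config": dataclasses.asdict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclasses.dataclass
class Scenario:
    """A packaged scenario: config + spikes + ids to run it against."""

    config: GeneratorConfig
    spikes: list
    library: MetaboliteLibrary
    protein_ids: list


def make_library(
    n_metabolites: int = 412,
    n_pools: int = 4,
    named: Sequence[str] = (),
) -> MetaboliteLibrary:
    """Build a screening library with round-robin pool assignment.

    ``named`` ids (if any) replace the first generated ids, so presets can
    refer to recognisable metabolites.
    """
    ids = [f"M{i + 1:04d}" for i in range(n_metabolites)]
    for i, name in enumerate(named):
        ids[i] = name
    entries = [
        MetaboliteEntry(metabolite_id=mid, name=mid, pool_id=(i % n_pools) + 1)
        for i, mid in enumerate(ids)
    ]
    return MetaboliteLibrary(entries)


def _fold_change_noise_variance(config: GeneratorConfig) -> float:
    """Analytic variance of a pair-mean log2 fold change from noise alone.

    Each dialysis-replicate fold change carries replicate noise from both
    chambers plus technical noise averaged over T injections per chamber;
    the pair mean averages R replicates.
    """
    r, t = config.replicate_noise_sd, config.tech_noise_sd
    return 2.0 * (r**2 + t**2 / config.n_tech_reps) / config.n_dialysis_reps


def _solve_latent_scale(config: GeneratorConfig, latent_unit: np.ndarray) -> float:
    """Mixing coefficient s so the latent share of fold-change variance
    hits the configured target; solved by a 1-D root find."""
    target = config.latent_variance_target
    if config.k_latent == 0 or target == 0:
        return 0.0
    var_n = _fold_change_noise_variance(config)
    v_l = float(latent_unit.var())
    if v_l == 0:
        return 0.0
    if var_n == 0:
        # noiseless screens have no variance for the latent term to share
        return 0.0

    def share_gap(s: float) -> float:
        lat = s * s * v_l
        return lat / (lat + var_n) - target

    hi = 1.0
    while share_gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("latent variance target unreachable")
    return float(brentq(share_gap, 0.0, hi, xtol=1e-12))


def generate_screen(
    config: GeneratorConfig,
    spikes: Sequence[SpikeSpec] = (),
    library: MetaboliteLibrary | None = None,
    protein_ids: Sequence[str] | None = None,
) -> tuple[MeasurementTable, SyntheticTruth]:
    """Generate one screen's injection table plus its ground truth.

    Per (protein, metabolite): the metabolite-chamber log2 abundance is
    ``baseline + replicate noise``; the protein chamber adds the latent
    term, the spike delta (if any) and its own replicate noise.  Technical
    injections add technical noise in log2 space, AUC = 2**log2abundance,
    and gross outliers multiply a random injection's AUC by
    ``2**outlier_magnitude`` at the configured rate.
    """
    P, M = config.n_proteins, config.n_metabolites
    R, T = config.n_dialysis_reps, config.n_tech_reps

    if library is None:
        library = make_library(M, config.n_pools)
    if len(library) != M:
        raise ValueError("library size does not match config.n_metabolites")
    if protein_ids is None:
        protein_ids = [f"P{i + 1:03d}" for i in range(P)]
    protein_ids = list(protein_ids)
    if len(protein_ids) != P:
        raise ValueError("protein_ids length does not match config.n_proteins")
    met_ids = library.ids

    pidx = {p: i for i, p in enumerate(protein_ids)}
    midx = {m: j for j, m in enumerate(met_ids)}
    delta = np.zeros((P, M))
    for s in spikes:
        if s.protein_id not in pidx:
            raise ValueError(f"spike references unknown protein {s.protein_id!r}")
        if s.metabolite_id not in midx:
            raise ValueError(f"spike references unknown metabolite {s.metabolite_id!r}")
        delta[pidx[s.protein_id], midx[s.metabolite_id]] += s.delta

    rng = np.random.default_rng(config.seed)
    lo, hi = config.baseline_log10_range
    baseline = rng.uniform(lo, hi, size=M) * np.log2(10.0)

    k = config.k_latent
    if k > 0:
        scores = rng.standard_normal((P, k))
        loadings = rng.standard_normal((k, M))
        latent_unit = scores @ loadings / np.sqrt(k)
    else:
        scores = np.zeros((P, 0))
        loadings = np.zeros((0, M))
        latent_unit = np.zeros((P, M))
    s_mix = _solve_latent_scale(config, latent_unit)

    rep_sd, tech_sd = config.replicate_noise_sd, config.tech_noise_sd
    prot_rep = rng.normal(0.0, 1.0, size=(P, M, R)) * rep_sd
    met_rep = rng.normal(0.0, 1.0, size=(P, M, R)) * rep_sd
    prot_tech = rng.normal(0.0, 1.0, size=(P, M, R, T)) * tech_sd
    met_tech = rng.normal(0.0, 1.0, size=(P, M, R, T)) * tech_sd

    log2_prot = (
        baseline[None, :, None]
        + (s_mix * latent_unit + delta)[:, :, None]
        + prot_rep
    )
    log2_met = baseline[None, :, None] + met_rep

    # chamber axis 0: 0 = metabolite, 1 = protein (alphabetical token order)
    log2_all = np.stack(
        [log2_met[..., None] + met_tech, log2_prot[..., None] + prot_tech], axis=0
    )
    auc = np.exp2(log2_all)

    out_mask = rng.random(size=auc.shape) < config.outlier_rate
    auc = np.where(out_mask, auc * 2.0**config.outlier_magnitude, auc)

    chamber_names = np.array(["metabolite", "protein"])
    c_ix, p_ix, m_ix, r_ix, t_ix = np.indices((2, P, M, R, T))
    frame = pd.DataFrame(
        {
            "protein_id": np.array(protein_ids, dtype=object)[p_ix.ravel()],
            "metabolite_id": np.array(met_ids, dtype=object)[m_ix.ravel()],
            "chamber": chamber_names[c_ix.ravel()],
            "dialysis_rep": r_ix.ravel() + 1,
            "tech_rep": t_ix.ravel() + 1,
            "auc": auc.ravel(),
        }
    )

    pos = np.argwhere(out_mask)
    outliers = pd.DataFrame(
        {
            "chamber": chamber_names[pos[:, 0]],
            "protein_id": [protein_ids[i] for i in pos[:, 1]],
            "metabolite_id": [met_ids[j] for j in pos[:, 2]],
            "dialysis_rep": pos[:, 3] + 1,
            "tech_rep": pos[:, 4] + 1,
        }
    )

    truth = SyntheticTruth(
        spikes=list(spikes),
        latent_scores=scores,
        latent_loadings=loadings,
        latent_scale=s_mix,
        outlier_positions=outliers,
        seed=config.seed,
        config=config,
    )
    return MeasurementTable(frame), truth


# ---------------------------------------------------------------------------
# Packaged DHTKD1-like scenario
# ---------------------------------------------------------------------------

#: Published screen readout for the five headline hDHTKD1 interactors:
#: corrected log2 fold change, p and q as printed.  These are inputs the
#: preset emulates and the stand-in table embeds.
DHTKD1_REPORTED = {
    "2OA": {"corrected_log2fc": -1.17, "p": 4.33e-54, "q": 2.59e-51},
    "2OG": {"corrected_log2fc": -0.28, "p": 0.17, "q": 0.74},
    "KIV": {"corrected_log2fc": -0.25, "p": 8.00e-4, "q": 2.06e-2},
    "dAMP": {"corrected_log2fc": 0.92, "p": 4.47e-11, "q": 4.84e-9},
    "dGMP": {"corrected_log2fc": 1.27, "p": 5.13e-18, "q": 1.07e-15},
}

PRESET_TARGET = "DHTKD1"
PRESET_METABOLITES = ("2OA_like", "2OG_like", "KIV_like", "dAMP_like", "dGMP_like")
PRESET_DELTAS = (-1.17, -0.28, -0.25, 0.92, 1.27)


def preset_dhtkd1_like(
    seed: int = 2020, zero_noise: bool = False, n_null_proteins: int = 60
) -> Scenario:
    """One target among null proteins, spiked with the five headline effects.

    The target protein carries a strong depletion (2OA-like, -1.17), two
    weak depletions (2OG-like -0.28, ketoisovalerate-like -0.25) and two
    enrichments (dAMP-like +0.92, dGMP-like +1.27).  With ``zero_noise``
    all noise sources and the latent structure are switched off, giving an
    analytically exact screen.
    """
    config = GeneratorConfig(n_proteins=n_null_proteins + 1, seed=seed)
    if zero_noise:
        config = dataclasses.replace(
            config,
            replicate_noise_sd=0.0,
            tech_noise_sd=0.0,
            outlier_rate=0.0,
            k_latent=0,
            latent_variance_target=0.0,
        )
    library = make_library(config.n_metabolites, config.n_pools, named=PRESET_METABOLITES)
    protein_ids = [PRESET_TARGET] + [f"NULL{i + 1:03d}" for i in range(n_null_proteins)]
    spikes = [
        SpikeSpec(PRESET_TARGET, met, d)
        for met, d in zip(PRESET_METABOLITES, PRESET_DELTAS)
    ]
    return Scenario(config=config, spikes=spikes, library=library, protein_ids=protein_ids)


def dhtkd1_reported_interactions() -> pd.DataFrame:
    """The five published hDHTKD1 pairs (corrected log2fc, p, q) as a frame."""
    rows = [
        {"metabolite_id": met, **vals} for met, vals in DHTKD1_REPORTED.items()
    ]
    return pd.DataFrame(rows)


def synthetic_s1_standin(seed: int = 0, n_metabolites: int = 412) -> pd.DataFrame:
    """SYNTHETIC stand-in for a deposited processed-screen table.

    The deposited supplementary screen file is not redistributable here, so
    this builds a schema-compatible substitute: the five published pairs
    with their printed corrected fold changes and p/q values, embedded in
    null filler rows drawn from the no-signal regime.  Use only for schema
    and significance-call checks, never as real data.
    """
    from scipy import stats as sps

    from .stats import storey_q

    rng = np.random.default_rng(seed)
    named = dhtkd1_reported_interactions()
    named["z"] = np.sign(named["corrected_log2fc"]) * sps.norm.isf(named["p"] / 2.0)
    n_null = n_metabolites - len(named)
    z = rng.standard_normal(n_null)
    null = pd.DataFrame(
        {
            "metabolite_id": [f"M{i + 1:04d}" for i in range(n_null)],
            "corrected_log2fc": np.round(z * 0.19, 4),
            "z": z,
            "p": 2.0 * sps.norm.sf(np.abs(z)),
        }
    )
    null["q"] = storey_q(null["p"].to_numpy(), pi0=1.0)
    out = pd.concat([named, null], ignore_index=True)
    out.insert(0, "protein_id", PRESET_TARGET)
    return out
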