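"""Synthetic connectomes, activation-state pairs, and cohorts.

Generates data with the statistical structure the analysis pipeline
assumes: modular FA-like weighted connectomes, paired low-demand /
high-demand activation patterns that differ in amplitude and spatial
spread, weight-preserving connectome degradation for a patient-like
group, and scalar standardized gene-score covariates with configurable
injected effects. Everything is seeded and writes plain CSV/JSON.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome, write_connectome

log = logging.getLogger(__name__)

__all__ = [
    "StatePair",
    "CohortTable",
    "make_connectome",
    "make_state_pair",
    "degrade_connectome",
    "make_cohort",
]

#: Beta-distribution concentration for FA-like edge weights in [0, 1]
_WEIGHT_KAPPA = 10.0
#: lognormal spread of per-subject high-demand amplitude
_AMP_LOG_SD = 0.05
#: rewire fraction injected per unit Cohen's d of the group stability effect
_REWIRE_PER_STABILITY_D = 0.55
#: rewire fraction injected per unit Cohen's d of the group energy effect
_REWIRE_PER_ENERGY_D = 0.55
_REWIRE_CAP = 0.8


@dataclass(frozen=True)
class StatePair:
    """Paired activation vectors for the two task conditions of a subject."""

    state_0back: np.ndarray
    state_2back: np.ndarray
    mean_activity_0: float
    mean_activity_2: float


@dataclass
class CohortTable:
    """A generated cohort: covariate table plus in-memory data objects.

    ``table`` has one row per subject (subject_id, group, age, sex, tsnr,
    d1_score, d2_score, amplitude and file-reference columns); ``states``
    and ``connectomes`` map subject_id to the generated objects.
    """

    table: pd.DataFrame
    states: dict = field(default_factory=dict)
    connectomes: dict = field(default_factory=dict)


def make_connectome(
    n_nodes: int = 374,
    n_modules: int = 8,
    intra_weight: float = 0.45,
    inter_weight: float = 0.15,
    density: float = 0.25,
    seed=None,
) -> Connectome:
    """Random modular weighted graph with FA-like weights in [0, 1].

    Edges appear independently with probability ``density``; weights are
    Beta draws with mean ``intra_weight`` inside modules and
    ``inter_weight`` between modules (intra > inter makes the graph
    modular). Modules are contiguous equal-size blocks of node indices.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be at least 2")
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    if not 1 <= n_modules <= n_nodes:
        raise ValueError(f"n_modules must be in [1, {n_nodes}]")
    if not 0.0 < inter_weight < 1.0 or not 0.0 < intra_weight < 1.0:
        raise ValueError("weights must be in (0, 1)")
    rng = np.random.default_rng(seed)
    module = np.repeat(np.arange(n_modules), math.ceil(n_nodes / n_modules))[:n_nodes]
    iu, ju = np.triu_indices(n_nodes, k=1)
    mu = np.where(module[iu] == module[ju], intra_weight, inter_weight)
    present = rng.random(iu.size) < density
    w = rng.beta(mu * _WEIGHT_KAPPA, (1.0 - mu) * _WEIGHT_KAPPA)
    vals = np.where(present, w, 0.0)
    W = np.zeros((n_nodes, n_nodes))
    W[iu, ju] = vals
    W[ju, iu] = vals
    return Connectome(W)


def make_state_pair(
    connectome: Connectome,
    amp0: float = 1.0,
    amp2: float = 3.0,
    spread0: float = 0.10,
    spread2: float = 0.40,
    noise_sd: float = 0.10,
    seed=None,
) -> StatePair:
    """Focal low-demand state and a broader, higher-amplitude one.

    Active supports are contiguous prefixes of the node ordering, which
    aligns them with the contiguous module blocks of
    :func:`make_connectome`: the low-demand support sits inside the first
    module and the high-demand support (which nests it) spans several.
    Equal spreads therefore give identical supports. Gaussian noise is
    added to every node independently per state.
    """
    n = connectome.n
    for name, s in (("spread0", spread0), ("spread2", spread2)):
        if not 0.0 < s <= 1.0:
            raise ValueError(f"{name} must be in (0, 1]")
    if amp0 <= 0 or amp2 <= 0:
        raise ValueError("amplitudes must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    c_noise0, c_noise2 = ss.spawn(2)
    k0 = math.ceil(spread0 * n)
    k2 = math.ceil(spread2 * n)
    x0 = np.zeros(n)
    x2 = np.zeros(n)
    x0[:k0] = amp0
    x2[:k2] = amp2
    if noise_sd > 0:
        x0 = x0 + np.random.default_rng(c_noise0).normal(0.0, noise_sd, n)
        x2 = x2 + np.random.default_rng(c_noise2).normal(0.0, noise_sd, n)
    return StatePair(
        state_0back=x0,
        state_2back=x2,
        mean_activity_0=float(x0.mean()),
        mean_activity_2=float(x2.mean()),
    )


def degrade_connectome(connectome: Connectome, rewire_fraction: float, seed=None) -> Connectome:
    """Randomly reassign a fraction of edge weights between node pairs.

    A seeded random subset of upper-triangle pairs (present or absent
    edges alike) has its weights permuted among itself, preserving
    symmetry, the zero diagonal, the exact weight multiset, and total
    strength, while destroying modular topology in proportion to
    ``rewire_fraction``.
    """
    if not 0.0 <= rewire_fraction <= 1.0:
        raise ValueError("rewire_fraction must be in [0, 1]")
    if rewire_fraction == 0.0:
        return Connectome(connectome.weights.copy(), connectome.labels)
    rng = np.random.default_rng(seed)
    n = connectome.n
    iu, ju = np.triu_indices(n, k=1)
    npairs = iu.size
    k = int(round(rewire_fraction * npairs))
    pick = rng.choice(npairs, size=k, replace=False)
    vals = connectome.weights[iu, ju].copy()
    vals[pick] = vals[pick][rng.permutation(k)]
    W = np.zeros_like(connectome.weights)
    W[iu, ju] = vals
    W[ju, iu] = vals
    return Connectome(W, connectome.labels)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def make_cohort(
    n_controls: int = 80,
    n_patients: int = 24,
    effect_sizes: dict | None = None,
    seed=None,
    out_dir=None,
    n_nodes: int = 374,
    n_modules: int = 8,
    density: float = 0.25,
    amp0: float = 1.0,
    amp2: float = 3.0,
    spread0: float = 0.10,
    spread2: float = 0.40,
    noise_sd: float = 0.10,
) -> CohortTable:
    """Generate a two-group cohort with configurable injected effects.

    ``effect_sizes`` keys (all optional, default 0):

    - ``stability_d``: target group difference (Cohen's d) in state
      stability, injected by degrading patient connectomes (weight
      multiset preserved, topology randomized).
    - ``energy_d``: target group difference in transition energy, injected
      through the same rewiring mechanism.
    - ``gene_slopes``: ``{"d1": r, "d2": r}`` correlations between the
      standardized gene scores and the subject-level amplitude deviations
      that drive stability (d1) and transition energy (d2).

    Patients additionally receive slightly lower tSNR, mirroring typical
    cohort tables. When ``out_dir`` is given, each subject's connectome
    and both state vectors are written as CSV (3 files per subject) plus
    ``cohort.csv`` and ``cohort_params.json``.
    """
    if n_controls < 2 or n_patients < 2:
        raise ValueError("need at least 2 subjects per group")
    effects = dict(effect_sizes or {})
    stability_d = float(effects.get("stability_d", 0.0))
    energy_d = float(effects.get("energy_d", 0.0))
    gene_slopes = dict(effects.get("gene_slopes", {}) or {})
    slope_d1 = float(gene_slopes.get("d1", 0.0))
    slope_d2 = float(gene_slopes.get("d2", 0.0))
    for name, s in (("d1", slope_d1), ("d2", slope_d2)):
        if not -1.0 <= s <= 1.0:
            raise ValueError(f"gene slope {name} must be in [-1, 1]")
    if not np.isfinite([stability_d, energy_d]).all():
        raise ValueError("effect sizes must be finite")

    rewire = _REWIRE_PER_STABILITY_D * abs(stability_d) + _REWIRE_PER_ENERGY_D * abs(energy_d)
    if rewire > _REWIRE_CAP:
        log.warning(
            "requested effects need rewire fraction %.2f; capped at %.2f "
            "(achieved effects will be smaller)", rewire, _REWIRE_CAP,
        )
        rewire = _REWIRE_CAP

    ss = np.random.SeedSequence(seed)
    n_total = n_controls + n_patients
    subject_streams = ss.spawn(n_total)
    cov_rng = np.random.default_rng(ss.spawn(1)[0])

    groups = ["control"] * n_controls + ["patient"] * n_patients
    rows = []
    states: dict[str, StatePair] = {}
    connectomes: dict[str, Connectome] = {}
    z2_all = np.empty(n_total)
    zd_all = np.empty(n_total)

    for idx, (group, sub_ss) in enumerate(zip(groups, subject_streams)):
        sid = f"sub-{idx:03d}"
        c_conn, c_rewire, c_state, c_amp = sub_ss.spawn(4)
        conn = make_connectome(
            n_nodes=n_nodes, n_modules=n_modules, density=density, seed=c_conn
        )
        if group == "patient" and rewire > 0:
            conn = degrade_connectome(conn, rewire, seed=c_rewire)
        amp_rng = np.random.default_rng(c_amp)
        z2 = float(amp_rng.normal())
        zd = float(amp_rng.normal())
        z2_all[idx] = z2
        zd_all[idx] = zd
        amp2_i = amp2 * math.exp(_AMP_LOG_SD * z2)
        amp0_i = amp0 * math.exp(_AMP_LOG_SD * (0.6 * z2 - 0.4 * zd))
        pair = make_state_pair(
            conn, amp0=amp0_i, amp2=amp2_i,
            spread0=spread0, spread2=spread2, noise_sd=noise_sd, seed=c_state,
        )
        tsnr_mean = 5.52 if group == "control" else 5.26
        rows.append({
            "subject_id": sid,
            "group": group,
            "age": float(np.clip(cov_rng.normal(33.0, 11.0), 18.0, 65.0)),
            "sex": int(cov_rng.integers(0, 2)),
            "tsnr": float(cov_rng.normal(tsnr_mean, 0.49)),
            "amp0": amp0_i,
            "amp2": amp2_i,
            "mean_activity_0": pair.mean_activity_0,
            "mean_activity_2": pair.mean_activity_2,
        })
        states[sid] = pair
        connectomes[sid] = conn

    # gene scores: standardized linear proxies of the amplitude deviations
    # that drive stability (z2) and transition demand (zd)
    gene_rng = np.random.default_rng(ss.spawn(1)[0])
    eps1 = gene_rng.normal(size=n_total)
    eps2 = gene_rng.normal(size=n_total)
    d1_raw = slope_d1 * (-z2_all) + math.sqrt(max(0.0, 1 - slope_d1**2)) * eps1
    d2_raw = slope_d2 * (-zd_all) + math.sqrt(max(0.0, 1 - slope_d2**2)) * eps2
    d1 = _standardize(d1_raw)
    d2 = _standardize(d2_raw)

    table = pd.DataFrame(rows)
    table["d1_score"] = d1
    table["d2_score"] = d2

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        conn_files, s0_files, s2_files = [], [], []
        for sid in table["subject_id"]:
            cf = out / f"{sid}_connectome.csv"
            write_connectome(connectomes[sid], cf)
            pair = states[sid]
            labels = connectomes[sid].labels
            for which, vec, files in (
                ("state0", pair.state_0back, s0_files),
                ("state2", pair.state_2back, s2_files),
            ):
                sf = out / f"{sid}_{which}.csv"
                pd.DataFrame({"region": labels, "value": vec}).to_csv(
                    sf, index=False, float_format="%.17g"
                )
                files.append(sf.name)
            conn_files.append(cf.name)
        table = table.assign(
            connectome_file=conn_files, state0_file=s0_files, state2_file=s2_files
        )
        table.to_csv(out / "cohort.csv", index=False, float_format="%.17g")
        params = {
            "n_controls": n_controls, "n_patients": n_patients,
            "n_nodes": n_nodes, "n_modules": n_modules, "density": density,
            "amp0": amp0, "amp2": amp2, "spread0": spread0, "spread2": spread2,
            "noise_sd": noise_sd, "rewire_fraction": rewire,
            "effect_sizes": {
                "stability_d": stability_d, "energy_d": energy_d,
                "gene_slopes": {"d1": slope_d1, "d2": slope_d2},
            },
            "seed": None if seed is None else int(seed),
        }
        with open(out / "cohort_params.json", "w") as fh:
            json.dump(params, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return CohortTable(table=table, states=states, connectomes=connectomes)
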