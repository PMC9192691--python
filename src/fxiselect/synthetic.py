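"""Synthetic two-timepoint VTE-like cohort with planted protein effects.

Generates a clinical table (covariates, medication flags, FXI:C outcome,
FXI antigen proxy, APTT) and an NPX-like protein abundance matrix with
correlated blocks, so that every downstream stage — exclusions, transforms,
fractional-polynomial LASSO selection, correlation-based query augmentation,
enrichment and network detection — can be exercised against a known truth.

Observations are indexed by ``"<subject_id>:<timepoint>"``; the clinical
table carries one row per (subject, timepoint) and the protein matrix is
aligned on the same index.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ACUTE = "acute"
FOLLOWUP = "followup"

#: supported planted effect shapes, applied to min-shifted positive values
EFFECT_SHAPES = ("linear", "log", "reciprocal", "quadratic")

FLAG_COLUMNS = {
    "history_dvt": 0.27,
    "history_pe": 0.11,
    "recent_immobilization": 0.14,
    "recent_surgery": 0.05,
    "recent_trauma": 0.04,
    "thrombophilia": 0.05,
    "atrial_fibrillation": 0.04,
    "congestive_heart_failure": 0.05,
    "coronary_artery_disease": 0.07,
    "chronic_kidney_disease": 0.06,
    "chronic_liver_disease": 0.05,
    "chronic_pulmonary_disease": 0.12,
}


class ConfigurationError(ValueError):
    """Raised when a :class:`SimulationConfig` violates its invariants."""


def default_protein_ids(n_proteins: int) -> list[str]:
    return [f"P{i:03d}" for i in range(1, n_proteins + 1)]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    By default three proteins act at both timepoints (``active_shared``)
    and three more act at each timepoint only; shapes mix linear and
    nonlinear dose-response forms. ``signal_r2`` is the target fraction of
    outcome variance explained by the planted protein effects.
    """

    n_acute: int = 549
    n_followup: int = 187
    n_overlap: int = 187
    n_proteins: int = 444
    block_size: int = 8
    block_rho: float = 0.5
    active_acute: tuple[str, ...] | None = None
    active_followup: tuple[str, ...] | None = None
    active_shared: tuple[str, ...] | None = None
    effect_shapes: dict[str, str] | None = None
    signal_r2: float = 0.35
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.15, "sex": -0.10, "bmi": 0.10}
    )
    doac_shift: float = -25.0
    doac_rate: float = 0.25
    aptt_slope: float = -0.10
    ag_rho: float = 0.22
    noise_sd: float | None = None
    malignancy_rate: float = 0.04
    low_fxi_rate: float = 0.01
    followup_attenuation: float = 0.7
    partner_mix: float = 0.92
    seed: int = 0

    def __post_init__(self) -> None:
        ids = default_protein_ids(self.n_proteins)
        # default actives: 9 proteins spread across blocks (3 shared,
        # 3 acute-only, 3 follow-up-only), as many as the matrix allows
        n_blocks = max(1, math.ceil(self.n_proteins / self.block_size))
        starts = sorted(
            {min(i * self.block_size, self.n_proteins - 1) for i in range(n_blocks)}
        )
        defaults = [ids[s] for s in starts[:9]]
        while len(defaults) < 9:  # tiny matrices: fill with remaining ids
            pool = [p for p in ids if p not in defaults]
            if not pool:
                break
            defaults.append(pool[0])
        if self.active_shared is None:
            self.active_shared = tuple(defaults[:3])
        if self.active_acute is None:
            self.active_acute = tuple(self.active_shared) + tuple(defaults[3:6])
        if self.active_followup is None:
            self.active_followup = tuple(self.active_shared) + tuple(defaults[6:9])
        if self.effect_shapes is None:
            shapes = {}
            cycle = ("linear", "log", "reciprocal", "quadratic")
            actives = sorted(set(self.active_acute) | set(self.active_followup))
            for i, pid in enumerate(actives):
                shapes[pid] = cycle[i % len(cycle)]
            self.effect_shapes = shapes
        self.validate()

    def validate(self) -> None:
        ids = set(default_protein_ids(self.n_proteins))
        if self.n_overlap > min(self.n_acute, self.n_followup):
            raise ConfigurationError(
                "n_overlap must not exceed min(n_acute, n_followup)"
            )
        if not set(self.active_shared) <= (
            set(self.active_acute) & set(self.active_followup)
        ):
            raise ConfigurationError(
                "active_shared must be a subset of active_acute ∩ active_followup"
            )
        for pid in set(self.active_acute) | set(self.active_followup):
            if pid not in ids:
                raise ConfigurationError(
                    f"active protein {pid!r} not among the {self.n_proteins} proteins"
                )
        if not 0.0 < self.signal_r2 < 1.0:
            raise ConfigurationError("signal_r2 must lie in (0, 1)")
        if not 0.0 <= self.block_rho < 1.0:
            raise ConfigurationError("block_rho must lie in [0, 1)")
        for pid, shape in (self.effect_shapes or {}).items():
            if shape not in EFFECT_SHAPES:
                raise ConfigurationError(f"unknown effect shape {shape!r} for {pid}")

    @property
    def protein_ids(self) -> list[str]:
        return default_protein_ids(self.n_proteins)

    def truth(self) -> dict:
        """Planted ground truth, suitable for JSON serialization."""
        return {
            "active_acute": sorted(self.active_acute),
            "active_followup": sorted(self.active_followup),
            "active_shared": sorted(self.active_shared),
            "effect_shapes": dict(sorted(self.effect_shapes.items())),
            "partners": {
                pid: partner for pid, partner in self._partner_map().items()
            },
            "signal_r2": self.signal_r2,
            "seed": self.seed,
        }

    def _partner_map(self) -> dict[str, str]:
        """One designated high-correlation partner per planted active protein."""
        ids = self.protein_ids
        index = {pid: i for i, pid in enumerate(ids)}
        actives = sorted(set(self.active_acute) | set(self.active_followup))
        active_set = set(actives)
        partners: dict[str, str] = {}
        taken: set[str] = set()
        for pid in actives:
            i = index[pid]
            block_start = (i // self.block_size) * self.block_size
            block = ids[block_start : block_start + self.block_size]
            candidates = [
                b for b in block if b != pid and b not in active_set and b not in taken
            ]
            if not candidates:  # fall back to any free protein
                candidates = [
                    b for b in ids if b != pid and b not in active_set and b not in taken
                ]
            if candidates:
                partners[pid] = candidates[0]
                taken.add(candidates[0])
        return partners


def _shaped(x: np.ndarray, shape: str) -> np.ndarray:
    """Apply an effect shape to the min-shifted positive version of ``x``.

    Mirrors the fractional-polynomial shift convention (x - min + 1) so the
    generator and the FP basis share one parameterization. The quadratic
    shape is centered, making it U-shaped (non-monotone): log and reciprocal
    are monotone and hence strongly rank-correlated with a linear term, so a
    genuinely nonlinear planted effect is needed to exercise the value of
    the basis expansion. It stays inside the span of the x and x^2 features.
    """
    xs = x - x.min() + 1.0
    if shape == "linear":
        return xs
    if shape == "log":
        return np.log(xs)
    if shape == "reciprocal":
        return 1.0 / xs
    if shape == "quadratic":
        return (xs - xs.mean()) ** 2
    raise ValueError(f"unknown shape {shape!r}")


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _protein_matrix(
    rng: np.random.Generator, n: int, cfg: SimulationConfig
) -> np.ndarray:
    """Exchangeable correlated blocks: x = sqrt(rho)*f_block + sqrt(1-rho)*e."""
    p = cfg.n_proteins
    n_blocks = math.ceil(p / cfg.block_size)
    factors = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, p))
    block_idx = np.repeat(np.arange(n_blocks), cfg.block_size)[:p]
    x = np.sqrt(cfg.block_rho) * factors[:, block_idx] + np.sqrt(
        1 - cfg.block_rho
    ) * eps
    return x


def _inject_partners(
    rng: np.random.Generator, x: np.ndarray, cfg: SimulationConfig
) -> None:
    """Overwrite designated partner columns so r >= ~partner_mix with actives."""
    index = {pid: i for i, pid in enumerate(cfg.protein_ids)}
    a = cfg.partner_mix
    for pid, partner in cfg._partner_map().items():
        noise = rng.standard_normal(x.shape[0])
        x[:, index[partner]] = a * x[:, index[pid]] + math.sqrt(1 - a * a) * noise


def _protein_signal(
    x: np.ndarray, active: tuple[str, ...], cfg: SimulationConfig
) -> np.ndarray:
    index = {pid: i for i, pid in enumerate(cfg.protein_ids)}
    if not active:
        return np.zeros(x.shape[0])
    parts = []
    for pid in sorted(active):
        shape = cfg.effect_shapes.get(pid, "linear")
        parts.append(_zscore(_shaped(x[:, index[pid]], shape)))
    return _zscore(np.sum(parts, axis=0))


def _spearman_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate normal achieving Spearman rho_s."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _outcome(
    rng: np.random.Generator,
    cov: pd.DataFrame,
    signal: np.ndarray,
    doac: np.ndarray,
    cfg: SimulationConfig,
    target_mean: float,
    target_sd: float = 34.0,
) -> np.ndarray:
    n = len(signal)
    cov_term = np.zeros(n)
    beta_sq = 0.0
    for name, beta in cfg.covariate_effects.items():
        if name in cov:
            cov_term += beta * _zscore(cov[name].to_numpy(dtype=float))
            beta_sq += beta * beta
    if cfg.noise_sd is None:
        noise_scale = math.sqrt(max(1.0 - cfg.signal_r2 - beta_sq, 0.01))
    else:
        noise_scale = cfg.noise_sd
    z = (
        cov_term
        + math.sqrt(cfg.signal_r2) * signal
        + noise_scale * _zscore(rng.standard_normal(n))
    )
    fxi = target_mean + target_sd * z / max(z.std(), 1e-12)
    fxi = fxi + cfg.doac_shift * doac
    return np.clip(fxi, 1.0, None)


def _clinical_frame(
    rng: np.random.Generator,
    subject_ids: list[str],
    timepoint: str,
    cfg: SimulationConfig,
    reuse: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw per-subject covariates; overlap subjects reuse acute covariates."""
    n = len(subject_ids)
    df = pd.DataFrame(index=pd.Index(subject_ids, name="subject_id"))
    df["sex"] = (rng.random(n) < 0.45).astype(int)
    df["age"] = np.round(np.clip(rng.normal(60.0, 16.0, n), 18, 95), 1)
    df["bmi"] = np.round(np.clip(rng.normal(28.0, 5.0, n), 16, 55), 1)
    for col, rate in FLAG_COLUMNS.items():
        df[col] = (rng.random(n) < rate).astype(int)
    df["active_malignancy"] = (rng.random(n) < cfg.malignancy_rate).astype(int)
    df["doac_user"] = (rng.random(n) < cfg.doac_rate).astype(int)
    df["thrombin_inhibitor"] = (rng.random(n) < 0.02).astype(int)
    df["heparin"] = (rng.random(n) < 0.55).astype(int)
    df["vka"] = (rng.random(n) < 0.06).astype(int)
    if reuse is not None:
        shared = [s for s in subject_ids if s in reuse.index]
        stable = [c for c in df.columns if c not in ("doac_user", "heparin")]
        df.loc[shared, stable] = reuse.loc[shared, stable]
    df["timepoint"] = timepoint
    return df


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the clinical table and protein matrix for both timepoints.

    Returns ``(cohort, proteins)``, both indexed by observation id
    ``"<subject>:<timepoint>"``. Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    acute_subjects = [f"S{i:04d}" for i in range(1, config.n_acute + 1)]
    overlap = acute_subjects[: config.n_overlap]
    n_new = config.n_followup - config.n_overlap
    new_subjects = [
        f"S{i:04d}" for i in range(config.n_acute + 1, config.n_acute + 1 + n_new)
    ]
    followup_subjects = overlap + new_subjects

    clin_acute = _clinical_frame(rng, acute_subjects, ACUTE, config)
    clin_fu = _clinical_frame(
        rng, followup_subjects, FOLLOWUP, config, reuse=clin_acute
    )

    x_acute = _protein_matrix(rng, config.n_acute, config)
    # follow-up latent values: attenuated reuse of acute latents for overlap
    x_fu = _protein_matrix(rng, config.n_followup, config)
    att = config.followup_attenuation
    pos = {s: i for i, s in enumerate(acute_subjects)}
    rows = [pos[s] for s in overlap]
    x_fu[: len(rows)] = att * x_acute[rows] + math.sqrt(1 - att * att) * x_fu[
        : len(rows)
    ]
    _inject_partners(rng, x_acute, config)
    _inject_partners(rng, x_fu, config)

    sig_acute = _protein_signal(x_acute, config.active_acute, config)
    sig_fu = _protein_signal(x_fu, config.active_followup, config)

    fxi_acute = _outcome(
        rng,
        clin_acute,
        sig_acute,
        clin_acute["doac_user"].to_numpy(float),
        config,
        target_mean=120.0,
    )
    fxi_fu = _outcome(
        rng,
        clin_fu,
        sig_fu,
        clin_fu["doac_user"].to_numpy(float),
        config,
        target_mean=87.0,
    )

    frames = []
    for clin, fxi, tp in ((clin_acute, fxi_acute, ACUTE), (clin_fu, fxi_fu, FOLLOWUP)):
        df = clin.copy()
        n = len(df)
        fxi = fxi.copy()
        # a small planted fraction with severe deficiency, to exercise exclusions
        n_low = int(round(config.low_fxi_rate * n))
        if n_low:
            low_idx = rng.choice(n, size=n_low, replace=False)
            fxi[low_idx] = rng.uniform(5.0, 19.5, size=n_low)
        df["fxi_c"] = np.round(fxi, 2)
        r = _spearman_pearson(config.ag_rho)
        ag = r * _zscore(fxi) + math.sqrt(1 - r * r) * _zscore(
            rng.standard_normal(n)
        )
        df["fxi_ag"] = np.round(ag, 4)
        aptt = (
            33.5
            + config.aptt_slope * (fxi - fxi.mean())
            + 4.0 * df["doac_user"].to_numpy(float)
            + rng.normal(0.0, 2.0, n)
        )
        df["aptt"] = np.round(np.clip(aptt, 15.0, None), 2)
        df["crp"] = np.round(np.exp(rng.normal(2.6, 1.1, n)), 2)
        df["platelets"] = np.round(np.clip(rng.normal(240.0, 60.0, n), 30, None), 1)
        df = df.reset_index()
        df.index = pd.Index(
            [f"{s}:{tp}" for s in df["subject_id"]], name="obs_id"
        )
        frames.append(df)
    cohort = pd.concat(frames)

    proteins = pd.DataFrame(
        np.vstack([x_acute, x_fu]),
        index=cohort.index,
        columns=config.protein_ids,
    ).round(6)
    return cohort, proteins


# ---------------------------------------------------------------------------
# fixtures for the enrichment / network stages
# ---------------------------------------------------------------------------


def generate_gene_sets(
    config: SimulationConfig, n_decoys: int = 20, set_size: int = 12, seed: int | None = None
) -> dict[str, list[str]]:
    """Synthetic GMT content with planted pathways covering the active sets.

    Planted sets contain the active proteins and their high-correlation
    partners plus random fill; decoy sets are random draws.
    """
    rng = np.random.default_rng(config.seed + 101 if seed is None else seed)
    ids = config.protein_ids
    partners = config._partner_map()
    sets: dict[str, list[str]] = {}

    def planted(name: str, actives: tuple[str, ...]) -> None:
        members = sorted(set(actives) | {partners[a] for a in actives if a in partners})
        pool = [p for p in ids if p not in members]
        fill = rng.choice(pool, size=max(set_size - len(members), 0), replace=False)
        sets[name] = sorted(members + list(fill))

    planted("PLANTED_SHARED", tuple(config.active_shared))
    planted("PLANTED_ACUTE", tuple(config.active_acute))
    planted("PLANTED_FOLLOWUP", tuple(config.active_followup))
    for k in range(n_decoys):
        members = rng.choice(ids, size=set_size, replace=False)
        sets[f"DECOY_{k:02d}"] = sorted(members)
    return sets


def generate_interactions(
    config: SimulationConfig, noise_p: float = 0.01, seed: int | None = None
) -> pd.DataFrame:
    """Synthetic PPI edge list: a physical clique over shared actives and
    partners, embedded in sparse random noise edges."""
    rng = np.random.default_rng(config.seed + 202 if seed is None else seed)
    ids = config.protein_ids
    partners = config._partner_map()
    core = sorted(
        set(config.active_shared)
        | {partners[a] for a in config.active_shared if a in partners}
    )
    rows = []
    for i, a in enumerate(core):
        for b in core[i + 1 :]:
            rows.append((a, b, 0.9, 1))
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if ids[i] in core and ids[j] in core:
                continue
            if rng.random() < noise_p:
                rows.append((ids[i], ids[j], round(float(rng.uniform(0.2, 0.7)), 3), int(rng.random() < 0.5)))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "physical"])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_fixtures(
    cohort: pd.DataFrame,
    proteins: pd.DataFrame,
    outdir: str | Path,
    truth: dict | None = None,
) -> dict[str, Path]:
    """Write cohort/protein CSVs (and optionally the truth JSON) to ``outdir``.

    The files round-trip losslessly through :func:`read_cohort` and
    :func:`read_proteins`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": outdir / "cohort.csv",
        "proteins": outdir / "proteins.csv",
    }
    try:
        cohort.to_csv(paths["cohort"], index=True)
        proteins.to_csv(paths["proteins"], index=True)
        if truth is not None:
            paths["truth"] = outdir / "truth.json"
            paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    except OSError as exc:
        raise OSError(f"failed writing fixtures under {outdir}: {exc}") from exc
    return paths


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="obs_id")
    return df


def read_proteins(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="obs_id")
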