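"""Synthetic data generator for the adaptive drug-response pipeline.

Generates datasets with the statistical structure the downstream analysis
assumes -- a low-rank latent "pathway activity" model coupling multiplexed
signaling measurements to cell viability -- together with a record of the
planted ground truth, so that every stage of the pipeline can be tested
without any external download.

The default configuration mirrors a dense perturbation study design:
10 cell lines x 5 drugs x 7 doses (1:3.16 dilution from 3.2 uM) x 5 signaling
time points (1, 5, 10, 24, 48 h) x 21 antibodies x 4 biological x 2 technical
replicates, scanned twice; phenotype counts at 24/48/72 h; bimodal single-cell
marker mixtures; and drug-combination grids with a planted excess over Bliss
independence.

Latent model
------------
Each cell line carries ``n_latent`` latent pathway activities. Latent ``l``
responds to drug ``g`` at dose ``d`` and time ``t`` as::

    a_l(g, d, t) = effect_size * occ(d; EC50_lg, h_lg) * phi_lg(t)

where ``occ`` is a Hill occupancy in [0, 1] (zero at dose 0) and ``phi`` is a
time profile that is -1 before a switch time and +/-1 after it, emulating
pathways that are down-regulated immediately after drug exposure and
re-activated (or not) at later times. Informative signals are linear
read-outs of one latent each on the log2 scale; measurement noise is additive
Gaussian on log2 (multiplicative on the raw scale). Non-apoptotic viability
relative to vehicle decays with the cumulative latent magnitude::

    v(g, d, t) = exp(-(t / 72 h) * sum_l beta_l * effect_size * occ_l(d))

so ``effect_size = 0`` gives flat signals and viability 1 everywhere.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SIGNALS",
    "SimConfig",
    "SyntheticTruth",
    "make_dose_grid",
    "make_truth",
    "generate_rppa",
    "generate_phenotype",
    "generate_single_cell",
    "generate_synergy",
    "write_truth_json",
]

#: Canonical 21-signal panel: 17 (phospho)signaling read-outs + 4 cell-state
#: markers (cPARP, pH3, p27, Bim), matching a typical RPPA melanoma panel.
DEFAULT_SIGNALS: tuple[str, ...] = (
    "pMEK", "pERK", "p90RSK_S380", "p90RSK_T573", "pAKT_T308", "pAKT_S473",
    "pmTOR", "p70S6K_T421", "p70S6K_T389", "pS6", "pAMPK", "pJNK", "cJun",
    "p-cJun", "p38", "pHSP27", "pNFkB", "pSTAT3", "cPARP", "pH3", "p27",
)[:21]

DEFAULT_DRUGS: tuple[str, ...] = (
    "vemurafenib", "PLX4720", "AZ628", "SB590885", "selumetinib",
)

CONTROL_LABEL = "DMSO"

_STAGES = ("truth", "rppa", "phenotype", "single_cell", "synergy")


def make_dose_grid(top_dose: float, ratio: float, n: int) -> np.ndarray:
    """Descending geometric dose series: ``top_dose / ratio**i`` for i = 0..n-1.

    A seven-point 1:3.16 series from 3.2 uM bottoms out at ~3.2 nM, spanning
    three orders of magnitude around typical kinase-inhibitor potencies.
    """
    if top_dose <= 0:
        raise ValueError("top_dose must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    if ratio <= 1:
        raise ValueError("ratio must be > 1")
    return top_dose / ratio ** np.arange(n)


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters for the synthetic generators.

    Doses are in uM, times in hours, noise on the log2 intensity scale.
    """

    n_cell_lines: int = 10
    drugs: tuple[str, ...] = DEFAULT_DRUGS
    n_doses: int = 7
    top_dose: float = 3.2
    dilution_ratio: float = 3.16
    times_signal: tuple[float, ...] = (1.0, 5.0, 10.0, 24.0, 48.0)
    times_pheno: tuple[float, ...] = (24.0, 48.0, 72.0)
    n_signals: int = 21
    n_bio_reps: int = 4
    n_tech_reps: int = 2
    n_latent: int = 3
    informative_fraction: float = 0.3
    noise_sd: float = 0.15
    effect_size: float = 1.0
    n_cells_per_condition: int = 2000
    mean_total_cells: float = 2000.0
    baseline_apoptosis: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_doses < 2:
            raise ValueError("n_doses must be >= 2")
        if self.dilution_ratio <= 1:
            raise ValueError("dilution_ratio must be > 1")
        if self.top_dose <= 0:
            raise ValueError("top_dose must be positive")
        for name in ("n_cell_lines", "n_signals", "n_bio_reps", "n_tech_reps",
                     "n_latent", "n_cells_per_condition"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.informative_fraction <= 1.0:
            raise ValueError("informative_fraction must be in [0, 1]")
        if len(self.drugs) < 1:
            raise ValueError("at least one drug required")

    @property
    def doses(self) -> np.ndarray:
        return make_dose_grid(self.top_dose, self.dilution_ratio, self.n_doses)

    @property
    def cell_lines(self) -> tuple[str, ...]:
        return tuple(f"CL{i + 1:02d}" for i in range(self.n_cell_lines))

    @property
    def signals(self) -> tuple[str, ...]:
        if self.n_signals == len(DEFAULT_SIGNALS):
            return DEFAULT_SIGNALS
        return tuple(f"sig{i + 1:02d}" for i in range(self.n_signals))


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    """One deterministic pseudorandom stream per generator stage."""
    idx = _STAGES.index(stage)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(idx,))
    )


def _hill(d: np.ndarray, ec50: float, h: float) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        occ = np.where(d > 0, d ** h / (d ** h + ec50 ** h), 0.0)
    return occ


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic study.

    Holds everything a test harness needs to check recovery: which
    (signal, time) variables were coupled to viability, the latent loadings
    and per-(cell line, drug, latent) Hill/time parameters, the viability
    link coefficients, the expected (noise-free) viability table, the
    single-cell mixture parameters, and the planted Bliss excess grid.
    """

    config: SimConfig
    informative_signals: tuple[str, ...]
    informative_variables: frozenset
    latent_loadings: pd.DataFrame            # latent x signal
    latent_params: pd.DataFrame              # (cell_line, drug, latent) rows
    viability_coef: pd.DataFrame             # (cell_line, latent) -> beta
    baseline_log2: pd.Series                 # per signal
    scanner_offset: pd.Series                # per signal, log2 additive (scanner B)
    expected_viability: pd.DataFrame         # cell_line, drug, dose, time, viability
    gate_truth: dict = field(default_factory=dict)
    synergy_truth: dict = field(default_factory=dict)

    # -- noise-free oracles ------------------------------------------------
    def latent_activity(self, cell_line: str, drug: str,
                        doses: np.ndarray, times: np.ndarray) -> np.ndarray:
        """Latent activities, shape (n_doses, n_times, n_latent)."""
        doses = np.asarray(doses, dtype=float)
        times = np.asarray(times, dtype=float)
        cfg = self.config
        out = np.zeros((doses.size, times.size, cfg.n_latent))
        for l in range(cfg.n_latent):
            p = self.latent_params.loc[(cell_line, drug, l)]
            occ = _hill(doses, p["ec50"], p["hill"])
            phi = np.where(times < p["switch_time"], -1.0, p["late_sign"])
            out[:, :, l] = cfg.effect_size * occ[:, None] * phi[None, :]
        return out

    def noiseless_log2(self, cell_line: str) -> pd.DataFrame:
        """Exact log2 fold change vs control per treated condition.

        Rows: (drug, dose) ordered by drug then descending dose.
        Columns: (signal, time).
        """
        cfg = self.config
        doses = cfg.doses
        rows = []
        index = []
        L = self.latent_loadings.to_numpy()  # latent x signal
        for drug in cfg.drugs:
            act = self.latent_activity(cell_line, drug, doses,
                                       np.asarray(cfg.times_signal))
            # (dose, time, latent) @ (latent, signal) -> (dose, time, signal)
            contrib = act @ L
            for i, d in enumerate(doses):
                rows.append(contrib[i].T.reshape(-1))  # signal-major
                index.append((drug, d))
        cols = pd.MultiIndex.from_product(
            [list(cfg.signals), list(cfg.times_signal)],
            names=["signal", "time"])
        idx = pd.MultiIndex.from_tuples(index, names=["drug", "dose"])
        return pd.DataFrame(rows, index=idx, columns=cols)

    def noiseless_viability(self, cell_line: str, time: float) -> pd.Series:
        """Expected non-apoptotic viability (fraction of vehicle) per condition."""
        tab = self.expected_viability
        sel = tab[(tab["cell_line"] == cell_line) & (tab["time"] == time)]
        idx = pd.MultiIndex.from_frame(sel[["drug", "dose"]])
        return pd.Series(sel["viability"].to_numpy(), index=idx, name="viability")

    def to_dict(self) -> dict:
        return {
            "config": dataclasses.asdict(self.config),
            "informative_signals": list(self.informative_signals),
            "informative_variables": sorted(
                [list(v) for v in self.informative_variables]),
            "latent_loadings": self.latent_loadings.to_dict(orient="split"),
            "latent_params": self.latent_params.reset_index().to_dict(
                orient="list"),
            "viability_coef": self.viability_coef.reset_index().to_dict(
                orient="list"),
            "baseline_log2": self.baseline_log2.to_dict(),
            "scanner_offset": self.scanner_offset.to_dict(),
            "expected_viability": self.expected_viability.to_dict(orient="list"),
            "gate_truth": self.gate_truth,
            "synergy_truth": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.synergy_truth.items()
            },
        }


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    """Write the planted ground truth as a documented JSON file."""
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, default=float))


def make_truth(config: SimConfig) -> SyntheticTruth:
    """Draw all planted parameters from the truth stream of the master seed."""
    rng = _rng(config, "truth")
    cfg = config
    signals = list(cfg.signals)

    n_info = int(round(cfg.informative_fraction * cfg.n_signals))
    n_info = max(min(n_info, cfg.n_signals), 0)
    info_idx = np.sort(rng.choice(cfg.n_signals, size=n_info, replace=False))
    informative_signals = tuple(signals[i] for i in info_idx)

    # one latent per informative signal; loading magnitude ~1, random sign
    loadings = np.zeros((cfg.n_latent, cfg.n_signals))
    for j, s in enumerate(info_idx):
        l = j % cfg.n_latent
        loadings[l, s] = rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0])
    latent_loadings = pd.DataFrame(
        loadings, index=pd.RangeIndex(cfg.n_latent, name="latent"),
        columns=signals)

    # Hill potency varies per (cell line, drug, latent); the direction
    # profile (switch time, late sign) is a property of the pathway within a
    # cell line, shared across drugs -- adaptive responses to mechanistically
    # similar inhibitors differ in potency, not direction. Drug-specific
    # directions would also decouple signals from viability linearly and
    # leave nothing for a regression model to find.
    lo, hi = np.log10(cfg.doses.min()), np.log10(cfg.doses.max())
    recs = []
    for cl in cfg.cell_lines:
        profile = [{"switch_time": float(rng.choice([0.0, 10.0, 24.0])),
                    "late_sign": float(rng.choice([-1.0, 1.0]))}
                   for _ in range(cfg.n_latent)]
        for drug in cfg.drugs:
            for l in range(cfg.n_latent):
                recs.append({
                    "cell_line": cl, "drug": drug, "latent": l,
                    "ec50": 10 ** rng.uniform(lo + 0.5, hi - 0.5),
                    "hill": rng.uniform(1.0, 3.0),
                    **profile[l],
                })
    latent_params = pd.DataFrame(recs).set_index(
        ["cell_line", "drug", "latent"])

    beta = rng.uniform(0.5, 1.5, size=(cfg.n_cell_lines, cfg.n_latent))
    beta /= cfg.n_latent  # keep total kill strength O(effect_size)
    viability_coef = pd.DataFrame(
        beta, index=pd.Index(cfg.cell_lines, name="cell_line"),
        columns=pd.RangeIndex(cfg.n_latent, name="latent"))

    baseline_log2 = pd.Series(rng.uniform(9.0, 13.0, cfg.n_signals),
                              index=signals, name="baseline_log2")
    scanner_offset = pd.Series(rng.normal(0.0, 0.05, cfg.n_signals),
                               index=signals, name="scanner_offset")

    # expected viability over phenotype times (time-scaled latent kill)
    vrecs = []
    doses = cfg.doses
    for cl in cfg.cell_lines:
        b = viability_coef.loc[cl].to_numpy()
        for drug in cfg.drugs:
            mag = np.zeros(doses.size)
            for l in range(cfg.n_latent):
                p = latent_params.loc[(cl, drug, l)]
                mag += b[l] * cfg.effect_size * _hill(doses, p["ec50"], p["hill"])
            for t in cfg.times_pheno:
                v = np.exp(-(t / 72.0) * mag)
                for d, vi in zip(doses, v):
                    vrecs.append({"cell_line": cl, "drug": drug, "dose": d,
                                  "time": t, "viability": vi})
    expected_viability = pd.DataFrame(vrecs)

    # times of maximal latent effect (all informative signals x all times)
    informative_variables = frozenset(
        (s, t) for s in informative_signals for t in cfg.times_signal)

    # single-cell mixture truth: two markers, High weight shifts with dose
    gate_truth = {}
    for marker, direction in (("p-cJun", +1.0), ("pRb", -1.0)):
        mu_low = rng.uniform(1.5, 2.5)
        gate_truth[marker] = {
            "mu_low": mu_low,
            "mu_high": mu_low + rng.uniform(2.0, 3.0),
            "sd_low": 0.5, "sd_high": 0.5,
            "w_high_base": rng.uniform(0.25, 0.45),
            "w_high_shift": 0.35,
            "ec50": 10 ** rng.uniform(lo + 1.0, hi - 1.0),
            "hill": 2.0,
            "direction": direction,
        }

    # synergy truth: two agents on the config dose grid, planted excess
    eps_peak = 0.15
    gx = _hill(doses, 10 ** rng.uniform(lo + 1.0, hi - 1.0), 2.0)
    gy = _hill(doses, 10 ** rng.uniform(lo + 1.0, hi - 1.0), 2.0)
    synergy_truth = {
        "drug_x": cfg.drugs[0], "drug_y": "JNK-IN-8",
        "doses_x": doses.copy(), "doses_y": doses.copy(),
        "emax_x": 0.6, "emax_y": 0.1,
        "shape_x": gx, "shape_y": gy,
        "eps": eps_peak * np.outer(gx, gy),
    }

    return SyntheticTruth(
        config=cfg,
        informative_signals=informative_signals,
        informative_variables=informative_variables,
        latent_loadings=latent_loadings,
        latent_params=latent_params,
        viability_coef=viability_coef,
        baseline_log2=baseline_log2,
        scanner_offset=scanner_offset,
        expected_viability=expected_viability,
        gate_truth=gate_truth,
        synergy_truth=synergy_truth,
    )


def _check_truth(config: SimConfig, truth: SyntheticTruth) -> None:
    if truth.config != config:
        raise ValueError("truth was generated under a different SimConfig")


def generate_rppa(config: SimConfig,
                  truth: SyntheticTruth | None = None
                  ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Replicate-level multiplex signaling tensor in long format.

    Returns a DataFrame with columns (cell_line, drug, dose, time, antibody,
    bio_rep, tech_rep, scanner, value) and the planted truth. Values are raw
    positive intensities ``2**(baseline + latent + noise)``; each physical
    replicate appears once per scanner (A/B) with independent read noise and a
    per-antibody scanner gain offset. Vehicle-control rows use drug "DMSO" at
    dose 0. Identical config (incl. seed) gives bit-identical output.
    """
    if truth is None:
        truth = make_truth(config)
    else:
        _check_truth(config, truth)
    cfg = config
    rng = _rng(cfg, "rppa")

    doses = cfg.doses
    conds = [(drug, d) for drug in cfg.drugs for d in doses]
    conds.append((CONTROL_LABEL, 0.0))
    n_cond, n_time, n_sig = len(conds), len(cfg.times_signal), cfg.n_signals
    n_rep = cfg.n_bio_reps * cfg.n_tech_reps
    scanners = ("A", "B")

    L = truth.latent_loadings.to_numpy()
    base = truth.baseline_log2.to_numpy()
    offs = truth.scanner_offset.to_numpy()
    times = np.asarray(cfg.times_signal)

    frames = []
    for cl in cfg.cell_lines:
        contrib = np.zeros((n_cond, n_time, n_sig))
        for gi, drug in enumerate(cfg.drugs):
            act = truth.latent_activity(cl, drug, doses, times)
            contrib[gi * cfg.n_doses:(gi + 1) * cfg.n_doses] = act @ L
        # control row stays zero
        mean_log2 = base[None, None, :] + contrib  # (cond, time, signal)
        for si, sc in enumerate(scanners):
            noise = rng.normal(0.0, cfg.noise_sd,
                               size=(n_cond, n_time, n_sig, n_rep))
            log2v = (mean_log2[..., None] + noise
                     + (offs[None, None, :, None] if si == 1 else 0.0))
            value = np.exp2(log2v).reshape(-1)
            drug_col = np.repeat([c[0] for c in conds], n_time * n_sig * n_rep)
            dose_col = np.repeat([c[1] for c in conds], n_time * n_sig * n_rep)
            time_col = np.tile(np.repeat(times, n_sig * n_rep), n_cond)
            ab_col = np.tile(np.repeat(np.asarray(cfg.signals), n_rep),
                             n_cond * n_time)
            bio_col = np.tile(np.repeat(np.arange(cfg.n_bio_reps) + 1,
                                        cfg.n_tech_reps), n_cond * n_time * n_sig)
            tech_col = np.tile(np.arange(cfg.n_tech_reps) + 1,
                               n_cond * n_time * n_sig * cfg.n_bio_reps)
            frames.append(pd.DataFrame({
                "cell_line": cl, "drug": drug_col, "dose": dose_col,
                "time": time_col, "antibody": ab_col, "bio_rep": bio_col,
                "tech_rep": tech_col, "scanner": sc, "value": value,
            }))
    tensor = pd.concat(frames, ignore_index=True)
    return tensor, truth


def generate_phenotype(config: SimConfig, truth: SyntheticTruth,
                       n_replicates: int | None = None) -> pd.DataFrame:
    """Phenotype count table: total and apoptotic cells per condition/time.

    ``total_cells ~ Poisson(mean_total_cells)`` and ``apoptotic_cells ~
    Binomial(total, p)`` with ``p = 1 - v * (1 - p0)`` chosen so that the
    expected non-apoptotic viability relative to vehicle equals the planted
    ``v`` exactly (``p0`` is the baseline apoptotic fraction in vehicle).
    """
    _check_truth(config, truth)
    cfg = config
    rng = _rng(cfg, "phenotype")
    n_rep = n_replicates if n_replicates is not None else cfg.n_bio_reps
    p0 = cfg.baseline_apoptosis

    ev = truth.expected_viability.set_index(
        ["cell_line", "drug", "dose", "time"])["viability"]

    recs = []
    for cl in cfg.cell_lines:
        for drug in list(cfg.drugs) + [CONTROL_LABEL]:
            dose_list = cfg.doses if drug != CONTROL_LABEL else [0.0]
            for d in dose_list:
                for t in cfg.times_pheno:
                    v = 1.0 if drug == CONTROL_LABEL else float(
                        ev.loc[(cl, drug, d, t)])
                    p = float(np.clip(1.0 - v * (1.0 - p0), 0.0, 1.0))
                    total = rng.poisson(cfg.mean_total_cells, size=n_rep)
                    apop = rng.binomial(total, p)
                    for r in range(n_rep):
                        recs.append((cl, drug, d, t, r + 1,
                                     int(total[r]), int(apop[r])))
    return pd.DataFrame(recs, columns=[
        "cell_line", "drug", "dose", "time", "replicate",
        "total_cells", "apoptotic_cells"])


def generate_single_cell(config: SimConfig, truth: SyntheticTruth,
                         cell_line: str | None = None,
                         n_cells: int | None = None) -> pd.DataFrame:
    """Single-cell marker intensity table from two-component log2-normal mixtures.

    One condition per dose of the first drug plus a vehicle control; per
    condition and marker, each cell's log2 intensity is drawn from the planted
    two-component normal mixture whose High-component weight shifts with dose.
    Columns: cell_line, condition, dose, cell_id, marker, intensity (raw).
    """
    _check_truth(config, truth)
    cfg = config
    rng = _rng(cfg, "single_cell")
    cl = cell_line if cell_line is not None else cfg.cell_lines[0]
    n = n_cells if n_cells is not None else cfg.n_cells_per_condition
    drug = cfg.drugs[0]

    conds = [(CONTROL_LABEL, 0.0)] + [(drug, d) for d in cfg.doses]
    frames = []
    for cond_drug, dose in conds:
        label = CONTROL_LABEL if cond_drug == CONTROL_LABEL else \
            f"{cond_drug}@{dose:.5g}uM"
        for marker, g in truth.gate_truth.items():
            shift = g["w_high_shift"] * g["direction"] * float(
                _hill(np.array([dose]), g["ec50"], g["hill"])[0])
            w_hi = float(np.clip(g["w_high_base"] + shift, 0.01, 0.99))
            hi = rng.random(n) < w_hi
            log2i = np.where(
                hi,
                rng.normal(g["mu_high"], g["sd_high"], n),
                rng.normal(g["mu_low"], g["sd_low"], n),
            )
            frames.append(pd.DataFrame({
                "cell_line": cl, "condition": label, "dose": dose,
                "cell_id": np.arange(n) + 1, "marker": marker,
                "intensity": np.exp2(log2i),
            }))
    return pd.concat(frames, ignore_index=True)


def generate_synergy(config: SimConfig, truth: SyntheticTruth,
                     noise_sd: float = 0.0) -> pd.DataFrame:
    """Drug-combination activity grid with a planted excess over Bliss.

    Single-agent activities (apoptotic fractions) follow Hill curves; the
    observed combination activity is the Bliss prediction plus the planted
    excess ``eps``, clipped to [0, 1]. Optional Gaussian noise (sd on the
    activity scale) may be added to the observed activity.
    """
    _check_truth(config, truth)
    rng = _rng(config, "synergy")
    st = truth.synergy_truth
    Ix = st["emax_x"] * np.asarray(st["shape_x"])
    Iy = st["emax_y"] * np.asarray(st["shape_y"])
    eps = np.asarray(st["eps"])
    pred = Ix[:, None] + Iy[None, :] - np.outer(Ix, Iy)
    obs = np.clip(pred + eps, 0.0, 1.0)
    if noise_sd > 0:
        obs = np.clip(obs + rng.normal(0.0, noise_sd, obs.shape), 0.0, 1.0)

    dx, dy = np.asarray(st["doses_x"]), np.asarray(st["doses_y"])
    recs = []
    for i, cx in enumerate(dx):
        for j, cy in enumerate(dy):
            recs.append((st["drug_x"], st["drug_y"], cx, cy,
                         Ix[i], Iy[j], obs[i, j]))
    return pd.DataFrame(recs, columns=[
        "drug_x", "drug_y", "dose_x", "dose_y",
        "activity_x", "activity_y", "activity_obs"])
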