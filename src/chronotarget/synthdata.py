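"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Emulates a short circadian RNA-seq design — seven samples taken every 4 h
over 24 h after a synchronization pulse — together with the auxiliary inputs
the downstream stages consume: a protein-interaction network with planted
hub genes, and per-time-point dose-response viability panels whose IC50
oscillates in phase with a target gene. Every generator is a pure function
of its configuration plus a seed and returns a ground-truth table so that
recovery tests can score the analysis stages.

Expression model
----------------
A rhythmic gene follows ``mesor * (1 + A * cos(2*pi*(t - phi)/period))``
with multiplicative lognormal noise (non-negative, heteroskedastic — the
shape of TPM-scale data). A 15-gene clock panel gets fixed canonical phases
(activators antiphase to repressors); clock-coupled genes are affine
transforms of a clock gene's series with noise tuned so the expected Pearson
correlation equals ``coupling_strength``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CLOCK_PANEL_PHASES",
    "SynthConfig",
    "generate_temporal_matrix",
    "generate_ppi_network",
    "generate_dose_response_panel",
    "four_pl",
]

# Canonical phase assignments (hours after synchronization) for the 15 genes
# of the core transcriptional/translational feedback loop. Activators
# (CLOCK/ARNTL and the RORs) peak near CT22-CT2, repressors (PERs/CRYs/NR1Ds)
# near CT8-CT12, giving the antiphase structure seen in synchronized cells.
CLOCK_PANEL_PHASES: dict[str, float] = {
    "ARNTL": 22.0,
    "CLOCK": 23.0,
    "NPAS2": 21.0,
    "RORA": 1.0,
    "RORB": 2.0,
    "RORC": 0.0,
    "PER1": 9.0,
    "PER2": 10.0,
    "PER3": 11.0,
    "CRY1": 12.0,
    "CRY2": 10.5,
    "NR1D1": 7.0,
    "NR1D2": 8.0,
    "DBP": 9.5,
    "NFIL3": 21.5,
}


@dataclass
class SynthConfig:
    """Configuration for the temporal expression generator.

    Parameters
    ----------
    n_genes:
        Number of non-clock background genes.
    time_points:
        Sampling grid in hours; strictly increasing. Default 0,4,...,24.
    n_replicates:
        Replicates per time point sharing the true waveform.
    frac_rhythmic:
        Fraction of background genes given a cosine waveform.
    period_h:
        True oscillation period in hours.
    amplitude_range:
        Bounds for the relative amplitude A drawn uniformly per gene.
    noise_cv:
        Coefficient of variation of the multiplicative lognormal noise.
    n_clock_genes:
        Size of the clock panel prepended to the matrix (<= 15).
    n_coupled:
        Number of rhythmic background genes made affine transforms of a
        randomly chosen clock gene.
    coupling_strength:
        Target Pearson correlation (by magnitude) between a coupled gene
        and its clock partner; sign drawn per gene.
    seed:
        Seed for the dedicated generator stream.
    """

    n_genes: int = 100
    time_points: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
    n_replicates: int = 1
    frac_rhythmic: float = 0.2
    period_h: float = 24.0
    amplitude_range: tuple[float, float] = (0.3, 0.8)
    noise_cv: float = 0.1
    n_clock_genes: int = 15
    n_coupled: int = 0
    coupling_strength: float = 0.9
    mesor_log_mean: float = 3.0
    mesor_log_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.frac_rhythmic <= 1.0:
            raise ValueError(f"frac_rhythmic must be in [0,1], got {self.frac_rhythmic}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        tp = np.asarray(self.time_points, dtype=float)
        if tp.ndim != 1 or len(tp) < 2 or np.any(np.diff(tp) <= 0):
            raise ValueError("time_points must be strictly increasing")
        if not -1.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must be in [-1,1]")
        if self.n_clock_genes > len(CLOCK_PANEL_PHASES):
            raise ValueError(f"n_clock_genes must be <= {len(CLOCK_PANEL_PHASES)}")
        if self.amplitude_range[0] <= 0:
            raise ValueError("amplitude_range lower bound must be > 0 for rhythmic genes")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def _cosine_series(t: np.ndarray, mesor: float, amp: float, phase: float, period: float) -> np.ndarray:
    return mesor * (1.0 + amp * np.cos(2 * np.pi * (t - phase) / period))


def generate_temporal_matrix(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a genes x (time, replicate) TPM matrix plus ground truth.

    Returns
    -------
    matrix:
        DataFrame indexed by gene id; columns ``CT{t}`` (single replicate)
        or ``CT{t}_r{j}``. Values are non-negative TPM-scale floats.
    truth:
        One row per gene with ``is_rhythmic``, ``true_phase``,
        ``true_amplitude``, ``coupled_clock_gene``, ``true_coupling_sign``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.time_points, dtype=float)
    n_t, n_rep = len(t), config.n_replicates

    n_obs = n_t * n_rep

    names: list[str] = []
    obs_rows: list[np.ndarray] = []  # observed (noisy) series per gene, length n_obs
    truth_rows: list[dict] = []

    def with_noise(clean: np.ndarray) -> np.ndarray:
        """Replicate a clean length-n_t waveform and apply lognormal noise."""
        full = np.repeat(clean, n_rep)
        return np.maximum(full * _lognormal_factor(rng, config.noise_cv, n_obs), 0.0)

    clock_names = list(CLOCK_PANEL_PHASES)[: config.n_clock_genes]
    clock_obs: dict[str, np.ndarray] = {}
    for name in clock_names:
        phase = CLOCK_PANEL_PHASES[name]
        mesor = float(rng.lognormal(config.mesor_log_mean, config.mesor_log_sd / 2))
        amp = float(rng.uniform(*config.amplitude_range))
        observed = with_noise(_cosine_series(t, mesor, amp, phase, config.period_h))
        clock_obs[name] = observed
        names.append(name)
        obs_rows.append(observed)
        truth_rows.append(
            dict(gene=name, is_rhythmic=True, true_phase=phase, true_amplitude=amp,
                 coupled_clock_gene="", true_coupling_sign="none")
        )

    n_rhythmic = int(round(config.frac_rhythmic * config.n_genes))
    n_coupled = min(config.n_coupled, n_rhythmic)
    if n_coupled > 0 and config.n_clock_genes == 0:
        raise ValueError("coupled genes require a clock panel")

    for i in range(config.n_genes):
        name = f"G{i:05d}"
        names.append(name)
        mesor = float(rng.lognormal(config.mesor_log_mean, config.mesor_log_sd))
        if i < n_coupled:
            # exact-correlation construction: standardize the partner's
            # observed series, add noise orthogonalized against it in-sample,
            # so the sample Pearson r equals coupling_strength exactly; an
            # affine map then sets the mesor and keeps values positive
            partner = clock_names[int(rng.integers(config.n_clock_genes))]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            z = clock_obs[partner]
            zc = z - z.mean()
            z_std = zc / np.linalg.norm(zc)
            e = rng.standard_normal(n_obs)
            e = e - e.mean() - (e @ z_std) * z_std
            c = abs(config.coupling_strength)
            if np.linalg.norm(e) > 0 and c < 1.0:
                e_std = e / np.linalg.norm(e)
                lam = np.sqrt(1.0 / c**2 - 1.0) if c > 0 else np.inf
                u = e_std if c == 0 else sign * (z_std + lam * e_std)
            else:
                u = sign * z_std
            u = u / np.max(np.abs(u))
            series = mesor * (1.0 + 0.5 * u)
            amp = float((series.max() - series.min()) / (2 * series.mean()))
            phase = CLOCK_PANEL_PHASES[partner]
            if sign < 0:
                phase = (phase + config.period_h / 2) % config.period_h
            obs_rows.append(series)
            truth_rows.append(
                dict(gene=name, is_rhythmic=True, true_phase=phase, true_amplitude=amp,
                     coupled_clock_gene=partner,
                     true_coupling_sign="+" if sign > 0 else "-")
            )
            continue
        if i < n_rhythmic:
            amp = float(rng.uniform(*config.amplitude_range))
            phase = float(rng.uniform(0.0, config.period_h)) % 24.0
            obs_rows.append(with_noise(_cosine_series(t, mesor, amp, phase, config.period_h)))
            truth_rows.append(
                dict(gene=name, is_rhythmic=True, true_phase=phase, true_amplitude=amp,
                     coupled_clock_gene="", true_coupling_sign="none")
            )
        else:
            obs_rows.append(with_noise(np.full(n_t, mesor)))
            truth_rows.append(
                dict(gene=name, is_rhythmic=False, true_phase=np.nan, true_amplitude=np.nan,
                     coupled_clock_gene="", true_coupling_sign="none")
            )

    if n_rep == 1:
        columns = [f"CT{t_i:g}" for t_i in t]
    else:
        columns = [f"CT{t_i:g}_r{j + 1}" for t_i in t for j in range(n_rep)]
    matrix = pd.DataFrame(np.vstack(obs_rows), index=pd.Index(names, name="gene"), columns=columns)
    truth = pd.DataFrame(truth_rows).set_index("gene")
    # internal consistency: flagged rhythmic implies positive amplitude
    bad = truth["is_rhythmic"] & ~(truth["true_amplitude"] > 0)
    if bad.any():
        raise ValueError(f"rhythmic gene with non-positive amplitude: {list(truth.index[bad])}")
    return matrix, truth


def generate_ppi_network(
    n_nodes: int,
    n_planted_hubs: int,
    clique_sizes: tuple[int, ...] = (6,),
    background_degree: int = 2,
    seed: int = 0,
    node_names: list[str] | None = None,
) -> tuple[nx.Graph, list[str]]:
    """Random background graph with planted hub nodes inside planted cliques.

    Each planted hub is the shared member of one planted clique per entry in
    ``clique_sizes`` and is additionally wired to enough random background
    nodes to have maximal degree in the graph. Background nodes form a
    random regular-ish graph of degree ``background_degree``.

    Returns the graph and the list of planted hub ids.
    """
    if n_planted_hubs > n_nodes:
        raise ValueError("n_planted_hubs must be <= n_nodes")
    for c in clique_sizes:
        if c < 3:
            raise ValueError("clique sizes must be >= 3")
        if c > n_nodes:
            raise ValueError("clique size larger than n_nodes")
    rng = np.random.default_rng(seed)
    if node_names is None:
        node_names = [f"N{i:04d}" for i in range(n_nodes)]
    if len(node_names) != n_nodes:
        raise ValueError("node_names length mismatch")

    g: nx.Graph = nx.Graph()
    g.add_nodes_from(node_names)
    hubs = node_names[:n_planted_hubs]
    pool = node_names[n_planted_hubs:]

    # sparse random background among non-hub nodes
    n_bg = len(pool)
    if n_bg >= 2 and background_degree > 0:
        n_edges = (n_bg * background_degree) // 2
        for _ in range(n_edges):
            i, j = rng.integers(0, n_bg, size=2)
            if i != j:
                g.add_edge(pool[i], pool[j])

    cursor = 0
    for hub in hubs:
        for c in clique_sizes:
            members = [hub]
            take = min(c - 1, max(0, len(pool) - cursor))
            members += pool[cursor : cursor + take]
            cursor += take
            for a, b in itertools.combinations(members, 2):
                g.add_edge(a, b)
        # hubs are both clique members and globally central: wire them to a
        # large fraction of the graph so path-based centralities dominate too
        target_deg = max(
            (max(dict(g.degree()).values()) if g.number_of_edges() else 0) + 3,
            round(0.3 * n_nodes),
        )
        extra = [p for p in pool if not g.has_edge(hub, p)]
        rng.shuffle(extra)
        for p in extra:
            if g.degree(hub) >= target_deg:
                break
            g.add_edge(hub, p)

    g.remove_edges_from(nx.selfloop_edges(g))
    return g, hubs


def four_pl(dose: np.ndarray, top: float, bottom: float, ic50: float, hill: float) -> np.ndarray:
    """Four-parameter logistic viability curve (decreasing in dose for hill > 0)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def generate_dose_response_panel(
    time_points=(0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0),
    doses=None,
    ic50_mesor: float = 1e-6,  # molar; mid-range of the default dilution series
    ic50_rel_amp: float = 0.3,
    ic50_phase: float = 8.0,
    hill: float = 1.0,
    top: float = 1.0,
    bottom: float = 0.0,
    noise_sd: float = 0.02,
    n_replicates: int = 3,
    period_h: float = 24.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-time-point 4PL viability panels with a cosine-modulated IC50.

    The IC50 at time t is ``ic50_mesor * (1 + ic50_rel_amp * cos(2*pi*(t -
    ic50_phase)/period_h))`` — highest IC50 (least drug kill, largest AUC)
    at ``ic50_phase``. Doses default to a 5-fold serial dilution over 10 uM
    to 16 nM in molar units, mirroring a standard viability assay layout.

    Returns a long-format frame with columns time_h, dose, replicate,
    viability.
    """
    if doses is None:
        doses = 10e-6 / 5.0 ** np.arange(7)[::-1]  # 16 nM ... 10 uM
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    if len(doses) < 5:
        raise ValueError("need >= 5 dose levels")
    if abs(ic50_rel_amp) >= 1:
        raise ValueError("ic50_rel_amp must be < 1 (IC50 would go non-positive)")
    rng = np.random.default_rng(seed)
    rows = []
    for t in time_points:
        ic50_t = ic50_mesor * (1.0 + ic50_rel_amp * np.cos(2 * np.pi * (t - ic50_phase) / period_h))
        clean = four_pl(doses, top, bottom, ic50_t, hill)
        for rep in range(1, n_replicates + 1):
            noisy = clean + rng.normal(0.0, noise_sd, size=len(doses))
            for d, v in zip(doses, noisy):
                rows.append(dict(time_h=float(t), dose=float(d), replicate=rep, viability=float(v)))
    return pd.DataFrame(rows)
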