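"""Synthetic study generator with planted ground truth.

The raw inputs of the plasma progression-signature study (pooled-plasma
peptide quantifications for four matched TNBC cohorts, a longitudinal
fast/slow mouse plasma series, TNBC cell-line spectral counts, scored
protein-interaction edge lists, and an expression + survival validation
cohort) are not publicly deposited.  This module emulates all five inputs
with a single seeded generator and records the planted truth, so every
downstream stage of the pipeline is testable end to end.

Conventions
-----------
* All randomness flows from one ``numpy.random.SeedSequence(seed)``;
  each sub-generator draws from a deterministically derived child stream,
  so individual tables are reproducible regardless of generation order.
* Measurement noise is multiplicative lognormal with unit mean: for a
  coefficient of variation ``cv`` the log-noise is
  ``Normal(-sigma^2/2, sigma)`` with ``sigma^2 = ln(1 + cv^2)``.  At
  ``cv=0`` every measurement is exact, which makes every downstream
  threshold's outcome exactly predictable from the planted effects.
* Pooled samples are simulated directly (one abundance per group), the
  mouse and human namespaces share uppercase symbols, and the survival
  baseline hazard is exponential.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .survival import risk_score, stratify

#: cohort labels: menopausal status x tumor stage, one pooled M/non-M pair each
COHORT_IDS: tuple[str, ...] = ("pre_II", "pre_III", "post_II", "post_III")

#: upstream-regulator symbols appended to synthetic interaction graphs
REGULATOR_SYMBOLS: tuple[str, ...] = ("TGFB1", "TNF")

CELL_LINE_IDS: tuple[str, ...] = (
    "HCC1937", "HCC1599", "HCC1806", "MDAMB468", "HCC70", "HCC1187",
    "HS578T", "BT549", "HCC1395", "HCC38", "MDAMB436", "BT20",
    "MDAMB157", "HMLER2", "HMLER3", "BPLER2", "BPLER3",
)

# child-stream tags (spawn keys appended to the root seed)
_STREAM_TRUTH = 0
_STREAM_COHORTS = 1
_STREAM_MOUSE = 2
_STREAM_GRAPH = 3
_STREAM_CELLS = 4
_STREAM_SECRETOME = 5
_STREAM_SURVIVAL = 6


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def protein_symbols(n: int) -> list[str]:
    """Synthetic gene-level protein symbols P0001..Pnnnn."""
    return [f"P{i + 1:04d}" for i in range(n)]


def _lognoise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise; exactly 1 when cv == 0."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the synthetic study.

    Scale anchors follow the original study where it states them: 1618
    quantified plasma proteins, 4 matched cohorts, a 210-patient survival
    validation cohort, 17 TNBC cell lines.  Effect sizes and noise levels
    the study does not report are fixed free parameters of the generator
    (see docs/methods.md), not tuning knobs.
    """

    n_proteins: int = 1618
    n_cohorts: int = 4
    n_up: int = 40
    n_down: int = 40
    effect_fc: float = 1.6
    n_effect_cohorts: int = 4           # cohorts in which the effect is planted (3 or 4)
    noise_cv: float = 0.2
    fraction_single_peptide: float = 0.30
    mean_extra_peptides: float = 2.0    # multi-peptide proteins have 2 + Poisson(mean)
    fraction_low_score: float = 0.15    # single-peptide ids with score < 6.0
    fraction_multi_mapped: float = 0.05
    # mouse series
    mouse_noise_cv: float = 0.1
    mouse_effect_f20: float = 1.6
    n_mouse_fast_extra: int = 20        # fast-planted proteins outside the human sets
    n_common_up: int = 6                # human-up proteins also planted mouse-fast
    n_common_down: int = 7
    n_signature: int = 3
    n_undetected_up: int = 3            # of the common-up set, not seen in cell lines
    n_undetected_down: int = 1
    # secretome
    n_secretome_up: int = 60
    n_secretome_down: int = 50
    # survival cohort
    n_patients: int = 210
    true_hr: float = 1.8
    censor_rate: float = 0.30
    baseline_hazard: float = math.log(2) / 5.0   # median ~5 years in the low group
    n_null_genes: int = 20
    tgfb_correlation: float = 0.45
    n_cell_lines: int = 17

    def __post_init__(self) -> None:
        if self.n_proteins < 10:
            raise ValueError("n_proteins must be at least 10")
        if self.effect_fc <= 1:
            raise ValueError("effect_fc must exceed 1 (planted fold change)")
        if self.mouse_effect_f20 <= 1:
            raise ValueError("mouse_effect_f20 must exceed 1")
        if self.true_hr <= 0:
            raise ValueError("true_hr must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        for name in ("noise_cv", "mouse_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("fraction_single_peptide", "fraction_low_score",
                     "fraction_multi_mapped"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 1 <= self.n_effect_cohorts <= self.n_cohorts:
            raise ValueError("n_effect_cohorts must lie in [1, n_cohorts]")
        planted = self.n_up + self.n_down + self.n_mouse_fast_extra
        if planted > self.n_proteins:
            raise ValueError("planted sets do not fit within n_proteins")
        if self.n_common_up > self.n_up or self.n_common_down > self.n_down:
            raise ValueError("human-mouse common sets exceed the planted human sets")
        if self.n_signature > self.n_common_up - self.n_undetected_up:
            raise ValueError("n_signature exceeds the detectable common-up proteins")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth of one simulated study, queryable per symbol."""

    up_proteins: frozenset[str]
    down_proteins: frozenset[str]
    null_proteins: frozenset[str]
    mouse_fast_proteins: frozenset[str]
    signature_genes: tuple[str, ...]
    cellline_undetected: frozenset[str]
    secretome_up: frozenset[str]
    secretome_down: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        if (self.up_proteins & self.down_proteins
                or self.up_proteins & self.null_proteins
                or self.down_proteins & self.null_proteins):
            raise ValueError("up/down/null planted sets must be pairwise disjoint")

    @property
    def all_proteins(self) -> frozenset[str]:
        return self.up_proteins | self.down_proteins | self.null_proteins

    def label(self, symbol: str) -> str:
        if symbol in self.up_proteins:
            return "up"
        if symbol in self.down_proteins:
            return "down"
        if symbol in self.null_proteins:
            return "null"
        raise KeyError(f"symbol without a truth label: {symbol}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            f.name: (sorted(v) if isinstance(v := getattr(self, f.name), frozenset)
                     else list(v) if isinstance(v, tuple) else v)
            for f in fields(self)
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        kwargs = {}
        for f in fields(cls):
            v = payload[f.name]
            if f.name == "signature_genes":
                kwargs[f.name] = tuple(v)
            elif isinstance(v, list):
                kwargs[f.name] = frozenset(v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)


def make_ground_truth(config: SimulationConfig, seed: int) -> GroundTruth:
    """Draw the planted sets once; all generators share this assignment.

    The common human/mouse proteins, the cell-line-undetected subset and
    the signature genes are nested so the refinement chain has an exact
    expected outcome: of ``n_common_up + n_common_down`` shared proteins,
    ``n_undetected_up + n_undetected_down`` are invisible in cell lines
    and the first ``n_signature`` detectable common-up proteins are the
    planted survival signature.
    """
    rng = _rng(seed, _STREAM_TRUTH)
    symbols = np.array(protein_symbols(config.n_proteins))
    picked = rng.choice(symbols,
                        size=config.n_up + config.n_down + config.n_mouse_fast_extra,
                        replace=False)
    picked = [str(s) for s in picked]
    up = sorted(picked[:config.n_up])
    down = sorted(picked[config.n_up:config.n_up + config.n_down])
    extra_fast = sorted(picked[config.n_up + config.n_down:])
    common_up = up[:config.n_common_up]
    common_down = down[:config.n_common_down]
    undetected = (common_up[config.n_signature:
                            config.n_signature + config.n_undetected_up]
                  + common_down[:config.n_undetected_down])
    signature = tuple(common_up[:config.n_signature])
    null = set(symbols) - set(up) - set(down)
    sec_pool = [s for s in symbols if s not in signature]
    sec = rng.choice(np.array(sec_pool),
                     size=config.n_secretome_up - len(signature) + config.n_secretome_down,
                     replace=False)
    sec = [str(s) for s in sec]
    sec_up = frozenset(signature) | frozenset(sec[:config.n_secretome_up - len(signature)])
    sec_down = frozenset(sec[config.n_secretome_up - len(signature):])
    return GroundTruth(
        up_proteins=frozenset(up),
        down_proteins=frozenset(down),
        null_proteins=frozenset(null),
        mouse_fast_proteins=frozenset(common_up) | frozenset(common_down)
        | frozenset(extra_fast),
        signature_genes=signature,
        cellline_undetected=frozenset(undetected),
        secretome_up=sec_up,
        secretome_down=sec_down,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# plasma cohorts
# ---------------------------------------------------------------------------

def generate_plasma_cohorts(
    config: SimulationConfig,
    seed: int,
    truth: GroundTruth | None = None,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Peptide-level quantification tables for the four matched cohorts.

    Each table has one row per peptide with columns ``peptide_id,
    protein_symbol, n_mapped_proteins, peptide_score, abundance_M,
    abundance_nonM, cohort_id``.  Planted up/down proteins carry an
    expected M/non-M ratio of ``effect_fc`` (resp. its inverse) in
    ``n_effect_cohorts`` of the cohorts and are always identified by at
    least two peptides, so single-peptide confidence filters never mask
    planted truth.
    """
    truth = truth if truth is not None else make_ground_truth(config, seed)
    rng = _rng(seed, _STREAM_COHORTS)
    symbols = protein_symbols(config.n_proteins)
    planted = truth.up_proteins | truth.down_proteins

    # peptide structure, shared across cohorts (same instrument/library)
    n_pept = np.where(
        rng.random(config.n_proteins) < config.fraction_single_peptide, 1,
        2 + rng.poisson(config.mean_extra_peptides, size=config.n_proteins))
    for i, s in enumerate(symbols):
        if s in planted and n_pept[i] < 2:
            n_pept[i] = 2 + rng.poisson(config.mean_extra_peptides)
    base_log2 = rng.normal(20.0, 3.0, size=config.n_proteins)

    prot_idx = np.repeat(np.arange(config.n_proteins), n_pept)
    n_rows = prot_idx.size
    pept_eff = rng.normal(0.0, 1.0, size=n_rows)
    base = np.exp2(base_log2[prot_idx] + pept_eff)

    # identification metadata
    score = rng.normal(9.0, 1.5, size=n_rows).clip(min=0.1)
    n_mapped = np.ones(n_rows, dtype=int)
    single = np.asarray(n_pept[prot_idx] == 1)
    low = rng.random(n_rows) < config.fraction_low_score
    score[single & low] = rng.uniform(2.0, 5.9, size=int((single & low).sum()))
    score[single & ~low] = rng.uniform(6.1, 12.0, size=int((single & ~low).sum()))
    multi_map = rng.random(n_rows) < config.fraction_multi_mapped
    n_mapped[multi_map] = rng.integers(2, 5, size=int(multi_map.sum()))

    # per-protein per-cohort planted fold change
    fc = np.ones((config.n_proteins, config.n_cohorts))
    for i, s in enumerate(symbols):
        if s in truth.up_proteins:
            val = config.effect_fc
        elif s in truth.down_proteins:
            val = 1.0 / config.effect_fc
        else:
            continue
        cols = (np.arange(config.n_cohorts) if config.n_effect_cohorts == config.n_cohorts
                else rng.choice(config.n_cohorts, size=config.n_effect_cohorts,
                                replace=False))
        fc[i, cols] = val

    sym_arr = np.array(symbols, dtype=object)[prot_idx]
    pept_ids = np.array([f"pep{j + 1:06d}" for j in range(n_rows)], dtype=object)
    cohorts: dict[str, pd.DataFrame] = {}
    for c, cid in enumerate(COHORT_IDS[:config.n_cohorts]):
        non_m = base * _lognoise(rng, config.noise_cv, n_rows)
        m = base * fc[prot_idx, c] * _lognoise(rng, config.noise_cv, n_rows)
        cohorts[cid] = pd.DataFrame({
            "peptide_id": pept_ids,
            "protein_symbol": sym_arr,
            "n_mapped_proteins": n_mapped,
            "peptide_score": np.round(score, 6),
            "abundance_M": m,
            "abundance_nonM": non_m,
            "cohort_id": cid,
        })
    return cohorts, truth


# ---------------------------------------------------------------------------
# mouse longitudinal series
# ---------------------------------------------------------------------------

def generate_mouse_series(
    config: SimulationConfig,
    seed: int,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Pooled-plasma abundances at baseline / prediagnostic-1 / -2.

    Fast-group planted proteins rise to ``mouse_effect_f20`` times
    baseline by the second prediagnostic draw (with an intermediate
    ``sqrt(effect)`` at the first); everything else is flat, so at zero
    noise F20 equals the planted ratio exactly and 1.0 otherwise.
    """
    truth = truth if truth is not None else make_ground_truth(config, seed)
    rng = _rng(seed, _STREAM_MOUSE)
    symbols = protein_symbols(config.n_proteins)
    planted = truth.mouse_fast_proteins
    rows = []
    base_log2 = rng.normal(18.0, 2.5, size=config.n_proteins)
    for group in ("fast", "slow"):
        for i, s in enumerate(symbols):
            base = 2.0 ** base_log2[i]
            if group == "fast" and s in planted:
                r1, r2 = math.sqrt(config.mouse_effect_f20), config.mouse_effect_f20
            else:
                r1 = r2 = 1.0
            noise = _lognoise(rng, config.mouse_noise_cv, 3)
            rows.append((s, group, base * noise[0], base * r1 * noise[1],
                         base * r2 * noise[2]))
    df = pd.DataFrame(rows, columns=["protein_symbol", "group", "baseline",
                                     "prediag1", "prediag2"])
    return df, truth


# ---------------------------------------------------------------------------
# interaction graph
# ---------------------------------------------------------------------------

_GRAPH_MODELS = ("scale_free", "complete", "erdos_renyi")


def generate_interaction_graph(
    n_nodes: int | None = None,
    model: str = "scale_free",
    seed: int = 0,
    symbols: Sequence[str] | None = None,
    m: int = 3,
    p: float = 0.05,
    include_regulators: bool = True,
) -> nx.Graph:
    """Scored interaction graph over the shared protein namespace.

    ``model`` is one of ``scale_free`` (Barabasi-Albert, degree exponent
    ~3), ``complete`` or ``erdos_renyi``.  Edges carry integer
    ``confidence`` in [1, 1000] (STRING scale) and ``provenance`` =
    ``database``.  When ``include_regulators`` is set, the upstream
    regulator symbols TGFB1 and TNF are appended to the node set.
    """
    if symbols is None:
        if n_nodes is None or n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        symbols = protein_symbols(n_nodes)
    symbols = list(symbols)
    if include_regulators:
        symbols = symbols + [r for r in REGULATOR_SYMBOLS if r not in symbols]
    n = len(symbols)
    if n < 2:
        raise ValueError("graph needs at least 2 nodes")
    if model not in _GRAPH_MODELS:
        raise ValueError(f"unknown degree model {model!r}; choose from {_GRAPH_MODELS}")
    ss = np.random.SeedSequence([int(seed), _STREAM_GRAPH])
    nx_seed = int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
    rng = np.random.default_rng(ss.spawn(1)[0])
    if model == "complete":
        g = nx.complete_graph(n)
    elif model == "scale_free":
        g = nx.barabasi_albert_graph(n, min(m, n - 1), seed=nx_seed)
    else:
        g = nx.gnp_random_graph(n, p, seed=nx_seed)
    g = nx.relabel_nodes(g, dict(enumerate(symbols)))
    conf = rng.integers(1, 1001, size=g.number_of_edges())
    for (u, v), c in zip(sorted(g.edges()), conf):
        g.edges[u, v]["confidence"] = int(c)
        g.edges[u, v]["provenance"] = "database"
    return g


# ---------------------------------------------------------------------------
# cell-line panel and secretome
# ---------------------------------------------------------------------------

def generate_cellline_panel(
    config: SimulationConfig,
    seed: int,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Spectral-count matrix (protein x 17 cell lines, total extracts).

    Proteins in ``truth.cellline_undetected`` are zero everywhere; every
    other protein has at least one nonzero line, so the tumor-intrinsic
    detection filter is exactly predictable from the truth.
    """
    truth = truth if truth is not None else make_ground_truth(config, seed)
    rng = _rng(seed, _STREAM_CELLS)
    symbols = protein_symbols(config.n_proteins)
    lines = list(CELL_LINE_IDS[:config.n_cell_lines])
    counts = rng.poisson(8.0, size=(config.n_proteins, len(lines)))
    # guarantee detection for everything not planted undetected
    zero_rows = counts.sum(axis=1) == 0
    counts[zero_rows, 0] = 1
    undetected = np.array([s in truth.cellline_undetected for s in symbols])
    counts[undetected] = 0
    df = pd.DataFrame(counts, index=pd.Index(symbols, name="protein_symbol"),
                      columns=lines)
    return df, truth


def generate_secretome_pairs(
    config: SimulationConfig,
    seed: int,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Conditioned-media ratio tables for the two metastatic/non-metastatic
    cell-line pairs (BPLER3/HMLER3 and BPLER2/HMLER2).

    Planted secretome-up proteins have ratio 2.0 (x noise) in both pairs,
    planted down 0.5, all others fluctuate mildly around 1.
    """
    truth = truth if truth is not None else make_ground_truth(config, seed)
    rng = _rng(seed, _STREAM_SECRETOME)
    symbols = protein_symbols(config.n_proteins)
    base = np.ones(config.n_proteins)
    base[[s in truth.secretome_up for s in symbols]] = 2.0
    base[[s in truth.secretome_down for s in symbols]] = 0.5
    out = {}
    for pair in ("BPLER3_HMLER3", "BPLER2_HMLER2"):
        jitter = (np.exp(rng.normal(0.0, 0.08, size=config.n_proteins))
                  if config.noise_cv > 0 else 1.0)
        out[pair] = base * jitter
    df = pd.DataFrame(out, index=pd.Index(symbols, name="protein_symbol"))
    return df, truth


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

def generate_survival_cohort(
    config: SimulationConfig,
    signature_genes: Sequence[str],
    seed: int,
) -> pd.DataFrame:
    """Expression + survival validation cohort under proportional hazards.

    Signature-gene expression shares a latent factor with TGFB1 (pairwise
    correlation ``tgfb_correlation``).  Patients are scored by the mean of
    standardized signature genes and the top quartile receives hazard
    ``baseline_hazard * true_hr`` (exponential event times); censoring is
    an independent exponential calibrated so that a fraction
    ``censor_rate`` of the low-risk group is expected censored.  Clinical
    covariates use raw codings (stage 1-4, menopause pre/post, grade 1-3,
    size in mm); see :func:`tgfbsig.survival.encode_clinical` for the
    dichotomies used in the models.
    """
    if not signature_genes:
        raise ValueError("signature_genes must be non-empty")
    if config.true_hr <= 0:
        raise ValueError("true_hr must be positive")
    rng = _rng(seed, _STREAM_SURVIVAL)
    n = config.n_patients
    rho = math.sqrt(config.tgfb_correlation)
    latent = rng.normal(size=n)
    expr = {
        g: rho * latent + math.sqrt(1 - rho * rho) * rng.normal(size=n)
        for g in signature_genes
    }
    expr["TGFB1"] = rho * latent + math.sqrt(1 - rho * rho) * rng.normal(size=n)
    for j in range(config.n_null_genes):
        expr[f"NULL{j + 1:03d}"] = rng.normal(size=n)
    df = pd.DataFrame(expr, index=[f"PT{i + 1:04d}" for i in range(n)])
    df.index.name = "patient_id"

    scores = risk_score(df, list(signature_genes), standardize=True)
    groups = stratify(scores, high_fraction=0.25)
    high = (groups.labels == "high").to_numpy()

    lam = config.baseline_hazard * np.where(high, config.true_hr, 1.0)
    t_event = rng.exponential(1.0 / lam)
    if config.censor_rate > 0:
        lam_c = config.baseline_hazard * config.censor_rate / (1 - config.censor_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    df["time"] = np.minimum(t_event, t_cens)
    df["event"] = (t_event <= t_cens).astype(int)
    df["stage"] = rng.choice([1, 2, 3, 4], size=n, p=[0.10, 0.45, 0.35, 0.10])
    df["menopause"] = rng.choice(["pre", "post"], size=n)
    df["grade"] = rng.choice([1, 2, 3], size=n, p=[0.10, 0.30, 0.60])
    df["size_mm"] = np.round(rng.lognormal(math.log(25.0), 0.4, size=n), 1)
    return df


# ---------------------------------------------------------------------------
# whole-study convenience wrapper
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """All synthetic inputs of one seeded run, plus the planted truth."""

    config: SimulationConfig
    truth: GroundTruth
    cohorts: dict[str, pd.DataFrame]
    mouse: pd.DataFrame
    graph: nx.Graph
    cellline_panel: pd.DataFrame
    secretome: pd.DataFrame
    survival: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every table in its on-disk dialect; returns the paths."""
        from . import io as tio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for cid, df in self.cohorts.items():
            paths[f"cohort_{cid}"] = p = outdir / f"cohort_{cid}.tsv"
            tio.write_tsv(df, p)
        paths["mouse"] = p = outdir / "mouse_series.tsv"
        tio.write_tsv(self.mouse, p)
        paths["edges"] = p = outdir / "edges.tsv"
        tio.write_edges_tsv(self.graph, p)
        paths["celllines"] = p = outdir / "cellline_counts.tsv"
        tio.write_tsv(self.cellline_panel.reset_index(), p)
        paths["secretome"] = p = outdir / "secretome_ratios.tsv"
        tio.write_tsv(self.secretome.reset_index(), p)
        paths["survival"] = p = outdir / "survival_cohort.csv"
        self.survival.to_csv(p)
        paths["annotations"] = p = outdir / "annotations.gmt"
        tio.write_gmt(self.annotation_sets(), p)
        paths["truth"] = p = outdir / "ground_truth.json"
        self.truth.to_json(p)
        return paths

    def annotation_sets(self) -> dict[str, set[str]]:
        """Truth-derived gene sets in GMT spirit, for enrichment demos."""
        rng = _rng(self.truth.seed, 7)
        symbols = protein_symbols(self.config.n_proteins)
        ann = {
            "planted_up": set(self.truth.up_proteins),
            "planted_down": set(self.truth.down_proteins),
            "mouse_fast": set(self.truth.mouse_fast_proteins),
        }
        for j in range(5):
            ann[f"random_set_{j + 1}"] = set(
                rng.choice(np.array(symbols), size=50, replace=False))
        return ann


def simulate_study(config: SimulationConfig | None = None, seed: int = 0,
                   ) -> SimulatedStudy:
    """Generate every pipeline input from one seed."""
    config = config or SimulationConfig()
    truth = make_ground_truth(config, seed)
    cohorts, _ = generate_plasma_cohorts(config, seed, truth)
    mouse, _ = generate_mouse_series(config, seed, truth)
    graph = generate_interaction_graph(symbols=protein_symbols(config.n_proteins),
                                       seed=seed)
    cells, _ = generate_cellline_panel(config, seed, truth)
    secretome, _ = generate_secretome_pairs(config, seed, truth)
    surv = generate_survival_cohort(config, truth.signature_genes, seed)
    return SimulatedStudy(config=config, truth=truth, cohorts=cohorts, mouse=mouse,
                          graph=graph, cellline_panel=cells, secretome=secretome,
                          survival=surv)
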