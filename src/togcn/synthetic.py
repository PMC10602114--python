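"""Two-condition time-course expression simulator with planted truth.

The generative model plants the temporal structure a TO-GCN is meant to
recover. Each of ``n_levels`` level groups carries a Gaussian activation
wave A_g * exp(-(t - c_k)^2 / (2 w^2)) sampled at ``n_timepoints``
points; consecutive level centers are spaced so that, at zero noise,
consecutive-level profiles correlate above the co-expression cutoff
while profiles >= 2 levels apart fall below it (the spacing is solved
numerically from the cutoff at generation time and recorded in the
truth). TF genes and level-co-expressed non-TF genes follow their
level's wave with independent truncated-Gaussian noise; background
genes are time-constant baselines spanning the dynamic range, so the
per-sample upper quartile is carried by non-temporal genes as in real
transcriptomes. Every sample additionally receives a log-normal
library-size factor, the between-sample artifact that upper-quartile
normalization removes.

In condition B, a chosen subset of TFs has its wave center offset by
``shift_levels`` level spacings, planting the condition-specific TFs the
comparison stage should detect. Annotation terms are planted onto chosen
levels' co-expressed genes (plus random background padding) alongside
random null terms. Everything is reproducible from one RNG seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .compare import CLASS_A, CLASS_B, LevelComparison
from .datatypes import ExpressionMatrix, GeneAnnotation, SampleTable
from .errors import ConfigError, ValidationError
from .network import TOGCN


def _default_terms() -> list[tuple[str, int, int]]:
    return [("term_early", 2, 30), ("term_mid", 6, 30), ("term_late", 10, 30)]


@dataclass
class SimConfig:
    """Simulation design; defaults emulate an 11-level, two-condition study.

    The earliest level carries a single TF: the method seeds its BFS at
    the first-upregulated TF, and under the level = distance + 1
    contract any co-expressed peer of the seed would necessarily land
    one level deeper, so a unique earliest gene is the configuration in
    which the planted order is recoverable exactly. ``tfs_per_level``
    applies to levels 2..n_levels.
    """

    n_levels: int = 11
    tfs_per_level: int = 5
    n_coexpressed_per_level: int = 20
    n_background_genes: int = 2000
    n_shifted_tfs: int = 20
    shift_levels: int = 4
    n_timepoints: int = 5
    replicates: int = 3
    wave_width: float = 0.8       # in timepoint units
    amplitude: float = 100.0      # TPM scale
    noise_sd: float = 0.1         # in units of each gene's amplitude
    pcc_cutoff: float = 0.92      # cutoff the level spacing is solved for
    library_size_sd: float = 0.15
    baseline_range: tuple[float, float] = (0.5, 500.0)
    condition_a: str = "embryonic"
    condition_b: str = "juvenile"
    planted_terms: list[tuple[str, int, int]] = field(default_factory=_default_terms)
    n_null_terms: int = 5
    null_term_size: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_levels", "tfs_per_level", "n_timepoints", "replicates"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in (
            "n_coexpressed_per_level", "n_background_genes", "n_shifted_tfs",
            "n_null_terms",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.wave_width <= 0 or self.amplitude <= 0:
            raise ConfigError("wave_width and amplitude must be > 0")
        if not (0 < self.pcc_cutoff < 1):
            raise ConfigError("pcc_cutoff must be in (0, 1)")
        if self.n_shifted_tfs and not (1 <= self.shift_levels <= self.n_levels - 1):
            raise ConfigError("shift_levels must be in [1, n_levels - 1]")
        if self.n_shifted_tfs:
            # level 1 holds only the seed TF (never shifted); every other
            # level must keep >= 1 unshifted TF so both chains stay complete
            feasible_levels = sum(
                1 for k in range(2, self.n_levels + 1)
                if k + self.shift_levels <= self.n_levels or k - self.shift_levels >= 2
            )
            keep = min(2, self.tfs_per_level)
            capacity = max(self.tfs_per_level - keep, 0) * feasible_levels
            if self.n_shifted_tfs > capacity:
                raise ConfigError(
                    f"cannot shift {self.n_shifted_tfs} TFs while keeping every level "
                    f"occupied: capacity is {capacity}"
                )
        for term, level, size in self.planted_terms:
            if not (1 <= level <= self.n_levels):
                raise ConfigError(f"planted term {term!r} targets level {level} out of range")
            if size < self.n_coexpressed_per_level:
                raise ConfigError(
                    f"planted term {term!r} size {size} is smaller than the level's "
                    f"co-expressed set ({self.n_coexpressed_per_level})"
                )


def solve_wave_spacing(
    wave_width: float,
    cutoff: float,
    n_levels: int,
    n_timepoints: int,
    noise_sd: float = 0.0,
    replicates: int = 1,
    min_margin: float = 0.015,
    noise_margin: float = 0.005,
) -> float:
    """Solve the level spacing from the co-expression cutoff.

    A spacing is feasible when, at zero noise on the sampled timepoint
    grid (centers placed symmetrically about the grid midpoint), every
    consecutive-level PCC exceeds the cutoff and every >= 2-apart PCC
    falls below it, each by ``min_margin`` (a deterministic guard that
    also absorbs the small residual distortion of between-sample
    normalization). Measurement noise attenuates observed correlations
    by roughly R = s^2 / (s^2 + sigma^2) per gene (s^2 the wave's
    variance across timepoints, sigma the replicate-mean noise sd). The
    dominant failure mode of BFS leveling under noise is a >= 2-apart
    pair fluctuating above the cutoff — a shortcut edge that deletes a
    rung of the level ladder — whereas an occasional sub-cutoff
    consecutive pair is absorbed by the other gene pairs bridging the
    same two levels. The solver therefore returns the feasible spacing
    minimizing the skip correlation among those keeping the attenuated
    consecutive correlation ``noise_margin`` above the cutoff; when the
    noise level makes that impossible the best-effort spacing maximizing
    the attenuated consecutive correlation is returned instead, so that
    degradation studies at high noise still have data to run on. Only
    the zero-noise geometry is a hard feasibility requirement.
    """
    if n_levels < 2:
        return wave_width  # single level: spacing is irrelevant
    t = np.arange(n_timepoints, dtype=float)
    sigma2 = (noise_sd / np.sqrt(replicates)) ** 2  # amplitude-1 units
    best_delta, best_skip = None, np.inf
    fallback_delta, fallback_consec = None, -np.inf
    best_infeasible = -np.inf
    for delta in np.linspace(0.02, 1.5, 400):
        c0 = (n_timepoints - 1) / 2.0 - delta * (n_levels - 1) / 2.0
        centers = c0 + np.arange(n_levels) * delta
        profiles = np.exp(-((t[None, :] - centers[:, None]) ** 2) / (2 * wave_width**2))
        if (profiles.std(axis=1) == 0).any():
            continue
        corr = np.corrcoef(profiles)
        consec = min(corr[i, i + 1] for i in range(n_levels - 1))
        if n_levels > 2:
            iu = np.triu_indices(n_levels, 2)
            skip = corr[iu].max()
        else:
            skip = -1.0
        s2 = profiles.var(axis=1).mean()
        atten = s2 / (s2 + sigma2)
        margin = min(consec - cutoff, cutoff - skip)
        best_infeasible = max(best_infeasible, margin)
        if margin < min_margin:
            continue
        if consec * atten > fallback_consec:
            fallback_delta, fallback_consec = float(delta), float(consec * atten)
        if consec * atten < cutoff + noise_margin:
            continue
        if skip < best_skip:
            best_delta, best_skip = float(delta), float(skip)
    if best_delta is None:
        best_delta = fallback_delta
    if best_delta is None:
        raise ConfigError(
            f"cannot separate {n_levels} levels around PCC cutoff {cutoff} with "
            f"wave_width={wave_width}, noise_sd={noise_sd} on {n_timepoints} "
            f"timepoints (best zero-noise margin {best_infeasible:.4f})"
        )
    return best_delta


def _seed_center_offset(
    wave_width: float,
    cutoff: float,
    delta: float,
    n_levels: int,
    n_timepoints: int,
    min_margin: float = 0.015,
) -> float:
    """Gap between the seed's wave center and level 2, as a fraction of delta.

    The whole level ladder hangs on the seed's link to level 2 — and
    level 1 holds only the seed — so that link is made the strongest in
    the chain: the seed sits as close before level 2 as it can while its
    correlation with level 3 and beyond stays below the cutoff.
    """
    if n_levels < 3:
        return 1.0
    t = np.arange(n_timepoints, dtype=float)
    mid = (n_timepoints - 1) / 2.0
    c0 = mid - delta * (n_levels - 1) / 2.0
    later = c0 + np.arange(2, n_levels) * delta  # centers of levels 3..n
    later_profiles = np.exp(-((t[None, :] - later[:, None]) ** 2) / (2 * wave_width**2))
    for gamma in np.linspace(0.25, 1.0, 76):
        c_seed = c0 + delta - gamma * delta
        seed_profile = np.exp(-((t - c_seed) ** 2) / (2 * wave_width**2))
        if seed_profile.std() == 0:
            continue
        corr = np.array(
            [np.corrcoef(seed_profile, lp)[0, 1] for lp in later_profiles]
        )
        if corr.max() < cutoff - min_margin:
            return float(gamma)
    return 1.0


@dataclass
class SyntheticTruth:
    """Planted ground truth written alongside a simulated dataset."""

    level_of: dict[str, int]            # condition-A planted level (TFs + co-expressed)
    level_of_b: dict[str, int]          # condition-B planted level (shifted TFs move)
    center_b: dict[str, float]          # condition-B wave center per leveled gene
    shifted: frozenset[str]             # TFs whose wave moved between conditions
    tf_genes: frozenset[str]
    term_level: dict[str, int]
    level_spacing: float
    rng_seed: int

    def to_dict(self) -> dict:
        return {
            "level_of": self.level_of,
            "level_of_b": self.level_of_b,
            "center_b": self.center_b,
            "shifted": sorted(self.shifted),
            "tf_genes": sorted(self.tf_genes),
            "term_level": self.term_level,
            "level_spacing": self.level_spacing,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            level_of={g: int(v) for g, v in d["level_of"].items()},
            level_of_b={g: int(v) for g, v in d["level_of_b"].items()},
            center_b={g: float(v) for g, v in d["center_b"].items()},
            shifted=frozenset(d["shifted"]),
            tf_genes=frozenset(d["tf_genes"]),
            term_level={t: int(v) for t, v in d["term_level"].items()},
            level_spacing=float(d["level_spacing"]),
            rng_seed=int(d["rng_seed"]),
        )


@dataclass
class SimResult:
    expr_a: ExpressionMatrix
    expr_b: ExpressionMatrix
    samples: SampleTable
    annotation: GeneAnnotation
    truth: SyntheticTruth
    config: SimConfig


def generate(config: SimConfig) -> SimResult:
    """Simulate a two-condition time course with planted temporal structure."""
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    t = np.arange(cfg.n_timepoints, dtype=float)
    delta = solve_wave_spacing(
        cfg.wave_width, cfg.pcc_cutoff, cfg.n_levels, cfg.n_timepoints,
        noise_sd=cfg.noise_sd, replicates=cfg.replicates,
    )
    c0 = (cfg.n_timepoints - 1) / 2.0 - delta * (cfg.n_levels - 1) / 2.0
    centers = {k: c0 + (k - 1) * delta for k in range(1, cfg.n_levels + 1)}
    if cfg.n_levels >= 2:
        gamma = _seed_center_offset(
            cfg.wave_width, cfg.pcc_cutoff, delta, cfg.n_levels, cfg.n_timepoints
        )
        centers[1] = centers[2] - gamma * delta

    tf_names = ["TF_L01_01"] + [
        f"TF_L{k:02d}_{i:02d}"
        for k in range(2, cfg.n_levels + 1)
        for i in range(1, cfg.tfs_per_level + 1)
    ]
    co_names = [
        f"CO_L{k:02d}_{i:03d}"
        for k in range(1, cfg.n_levels + 1)
        for i in range(1, cfg.n_coexpressed_per_level + 1)
    ]
    bg_names = [f"BG_{i:05d}" for i in range(1, cfg.n_background_genes + 1)]
    genes = tf_names + co_names + bg_names

    level_of: dict[str, int] = {}
    for name in tf_names + co_names:
        level_of[name] = int(name[4:6])

    # choose shifted TFs and, per TF, a shift direction (earlier or later in
    # condition B) — both condition-specific classes are populated, as in a
    # real dual-condition comparison. Arrivals at level 1 are forbidden so
    # the seed stays unique, and every level keeps the majority of its TFs
    # unshifted so level identity is never carried by a single gene.
    shifted: list[str] = []
    shift_dir: dict[str, int] = {}
    if cfg.n_shifted_tfs:
        eligible = [
            g for g in tf_names
            if level_of[g] >= 2
            and (level_of[g] + cfg.shift_levels <= cfg.n_levels
                 or level_of[g] - cfg.shift_levels >= 2)
        ]
        order = list(rng.permutation(len(eligible)))
        keep = min(2, cfg.tfs_per_level)
        per_level_left = {
            k: cfg.tfs_per_level - keep for k in range(1, cfg.n_levels + 1)
        }
        for idx in order:
            g = eligible[idx]
            if per_level_left[level_of[g]] > 0:
                dirs = [
                    d for d in (+1, -1)
                    if 2 <= level_of[g] + d * cfg.shift_levels <= cfg.n_levels
                ]
                shifted.append(g)
                shift_dir[g] = int(dirs[rng.integers(len(dirs))])
                per_level_left[level_of[g]] -= 1
            if len(shifted) == cfg.n_shifted_tfs:
                break
        if len(shifted) < cfg.n_shifted_tfs:
            raise ConfigError("could not place all shifted TFs")  # pragma: no cover
    shifted_set = frozenset(shifted)

    amp = np.full(len(tf_names) + len(co_names), cfg.amplitude)
    lo, hi = cfg.baseline_range
    baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_background_genes))

    rows_meta = []
    for idx, name in enumerate(tf_names + co_names):
        ca = centers[level_of[name]]
        cb = ca + shift_dir.get(name, 0) * cfg.shift_levels * delta
        rows_meta.append((name, amp[idx], ca, cb))
    center_b = {name: cb for name, _, _, cb in rows_meta}

    sample_rows = []
    for cond in (cfg.condition_a, cfg.condition_b):
        for j in range(cfg.n_timepoints):
            for rep in range(1, cfg.replicates + 1):
                sample_rows.append(
                    {
                        "sample_id": f"{cond}_T{j + 1}_r{rep}",
                        "condition": cond,
                        "timepoint": f"T{j + 1}",
                        "order": j + 1,
                        "replicate": rep,
                    }
                )
    samples = SampleTable(pd.DataFrame(sample_rows))
    n_per_cond = cfg.n_timepoints * cfg.replicates
    lib_factors = np.exp(rng.normal(0.0, cfg.library_size_sd, size=2 * n_per_cond))

    def _condition_matrix(which: str, offset: int) -> pd.DataFrame:
        n_wave = len(rows_meta)
        means = np.empty((len(genes), cfg.n_timepoints))
        gene_sd = np.empty(len(genes))
        for i, (name, a, ca, cb) in enumerate(rows_meta):
            c = ca if which == "A" else cb
            means[i] = a * np.exp(-((t - c) ** 2) / (2 * cfg.wave_width**2))
            gene_sd[i] = cfg.noise_sd * a
        means[n_wave:] = baselines[:, None]
        gene_sd[n_wave:] = cfg.noise_sd * baselines
        rep_means = np.repeat(means, cfg.replicates, axis=1)
        noise = rng.normal(0.0, 1.0, size=rep_means.shape) * gene_sd[:, None]
        vals = np.clip(rep_means + noise, 0.0, None)
        vals *= lib_factors[offset:offset + n_per_cond][None, :]
        cond = cfg.condition_a if which == "A" else cfg.condition_b
        cols = samples.samples_in_time_order(cond)
        return pd.DataFrame(vals, index=genes, columns=cols)

    expr_a = ExpressionMatrix(_condition_matrix("A", 0), "TPM")
    expr_b = ExpressionMatrix(_condition_matrix("B", n_per_cond), "TPM")

    term_sets: dict[str, set[str]] = {}
    term_desc: dict[str, str] = {}
    term_level: dict[str, int] = {}
    for term, level, size in cfg.planted_terms:
        members = {g for g in co_names if level_of[g] == level}
        pad = size - len(members)
        if pad > 0:
            extra = rng.choice(cfg.n_background_genes, size=pad, replace=False)
            members |= {bg_names[i] for i in extra}
        term_sets[term] = members
        term_desc[term] = f"planted at level {level}"
        term_level[term] = level
    non_tf = co_names + bg_names
    for j in range(cfg.n_null_terms):
        pick = rng.choice(len(non_tf), size=min(cfg.null_term_size, len(non_tf)), replace=False)
        name = f"null_term_{j + 1:02d}"
        term_sets[name] = {non_tf[i] for i in pick}
        term_desc[name] = "random gene set"
    annotation = GeneAnnotation(
        tf_set=set(tf_names), term_sets=term_sets, term_desc=term_desc
    )
    level_of_b = {
        g: lv + shift_dir.get(g, 0) * cfg.shift_levels
        for g, lv in level_of.items()
    }
    truth = SyntheticTruth(
        level_of=level_of,
        level_of_b=level_of_b,
        center_b=center_b,
        shifted=shifted_set,
        tf_genes=frozenset(tf_names),
        term_level=term_level,
        level_spacing=delta,
        rng_seed=cfg.rng_seed,
    )
    return SimResult(expr_a, expr_b, samples, annotation, truth, cfg)


def write_dataset(sim: SimResult, outdir) -> dict[str, str]:
    """Write the dataset as plain-text artifacts; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    combined = ExpressionMatrix(
        pd.concat([sim.expr_a.values, sim.expr_b.values], axis=1), sim.expr_a.unit
    )
    paths = {
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "tf_list": outdir / "tfs.txt",
        "gmt": outdir / "terms.gmt",
        "truth_tsv": outdir / "truth.tsv",
        "truth_json": outdir / "truth.json",
        "sim_config": outdir / "sim_config.json",
    }
    io.write_expression(combined, paths["expression"])
    io.write_samples(sim.samples, paths["samples"])
    io.write_tf_list(sim.annotation.tf_set, paths["tf_list"])
    io.write_gmt(sim.annotation, paths["gmt"])
    truth_rows = []
    for g in sorted(sim.truth.level_of):
        truth_rows.append(
            f"{g}\t{sim.truth.level_of[g]}\t{sim.truth.level_of_b[g]}"
            f"\t{int(g in sim.truth.shifted)}\t{sim.truth.center_b[g]!r}"
        )
    paths["truth_tsv"].write_text(
        "gene_id\tlevel_a\tlevel_b\tshifted\tcenter_b\n" + "\n".join(truth_rows) + "\n"
    )
    io.write_results_json(sim.truth.to_dict(), paths["truth_json"])
    io.write_results_json(dataclasses.asdict(sim.config), paths["sim_config"])
    return {k: str(v) for k, v in paths.items()}


def evaluate_recovery(result, truth: SyntheticTruth, condition: str = "A") -> dict:
    """Score an inferred TO-GCN or a two-condition comparison against truth.

    For a TO-GCN (or gene -> level mapping): Spearman correlation between
    inferred and planted levels over the genes leveled in both, plus the
    exact-match fraction; ``condition`` ("A" or "B") selects which
    condition's planted levels to score against, since shifted TFs are
    planted at different levels in the two conditions. For a
    LevelComparison: sensitivity/specificity of the specific-vs-common
    call against the planted shifted-TF set, counting unassigned TFs as
    non-detections.
    """
    from scipy import stats

    if isinstance(result, LevelComparison):
        table = result.table
        scored = set(table.index) & set(truth.tf_genes)
        if not scored:
            raise ValidationError("comparison and truth share no TF genes")
        classified = {
            g for g in scored if table.loc[g, "tf_class"] != "unassigned"
        }
        specific = {
            g for g in classified if table.loc[g, "tf_class"] in (CLASS_A, CLASS_B)
        }
        pos = set(truth.shifted)
        neg = set(truth.tf_genes) - pos
        pos_cls, neg_cls = pos & classified, neg & classified
        tp = len(specific & pos_cls)
        tn = len(neg_cls - specific)
        # sensitivity/specificity are conditional on a TF being leveled in
        # both networks; detection_rate counts unassigned shifted TFs as
        # misses, and the unassigned count is always reported alongside
        return {
            "kind": "comparison",
            "n_tfs": len(truth.tf_genes),
            "n_shifted": len(pos),
            "n_unassigned": len(scored - classified),
            "sensitivity": tp / len(pos_cls) if pos_cls else float("nan"),
            "specificity": tn / len(neg_cls) if neg_cls else float("nan"),
            "detection_rate": tp / len(pos) if pos else float("nan"),
        }

    if condition not in ("A", "B"):
        raise ConfigError(f"condition must be 'A' or 'B', got {condition!r}")
    planted_levels = truth.level_of if condition == "A" else truth.level_of_b
    inferred = dict(result.level_of) if isinstance(result, TOGCN) else dict(result)
    common = sorted(set(inferred) & set(planted_levels))
    if not common:
        raise ValidationError("inferred levels and truth share no genes")
    got = np.array([inferred[g] for g in common], dtype=float)
    want = np.array([planted_levels[g] for g in common], dtype=float)
    if len(common) < 2 or got.std() == 0 or want.std() == 0:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(got, want).statistic)
    n_unassigned = len(result.excluded) if isinstance(result, TOGCN) else 0
    return {
        "kind": "levels",
        "n_scored": len(common),
        "n_unassigned": n_unassigned,
        "spearman": rho,
        "exact_match_fraction": float((got == want).mean()),
    }
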