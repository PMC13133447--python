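"""Configuration, file round-tripping, and pipeline orchestration.

The pipeline defaults consolidate the analysis constants: 0.1-40 Hz
broadband and 1-20 Hz analysis band-passes (2nd order, zero phase), 250 Hz
analysis rate, 60-s epochs, -100..1000 ms lags, a 2^-5..2^15 lambda grid,
-100..-4 ms baseline, cluster alpha .05 with 1000 permutations and 4 cm
electrode adjacency, and peak windows 50-150 / 150-250 / 200-1000 ms.

:func:`run_pipeline` executes the full analysis on a simulated cohort:
feature assembly -> preprocessing -> group-level lambda selection ->
per-condition TRFs (acoustic and full) -> surprisal added-value test ->
within-group cluster tests on the surprisal kernel -> N1/P2/N400 peak
measures and group comparisons -> behavioral statistics and brain-behavior
Spearman correlations with FDR, writing every table plus a provenance log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import simulate as sim
from . import stats as st
from . import trf as trf_mod
from .surprisal import Token, validate_tokens

__all__ = [
    "PipelineConfig",
    "read_word_timing",
    "write_word_timing",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline constants in one auditable structure (YAML round-trip)."""

    out_dir: str = "semtrf_output"
    seed: int = 0
    # preprocessing
    broadband_hz: tuple[float, float] = (0.1, 40.0)
    analysis_band_hz: tuple[float, float] = (1.0, 20.0)
    filter_order: int = 2
    analysis_rate: float = 250.0
    trial_s: float = 60.0
    # TRF
    lag_window_ms: tuple[float, float] = (-100.0, 1000.0)
    lambda_grid_log2: tuple[int, int] = (-5, 15)
    baseline_ms: tuple[float, float] = (-100.0, -4.0)
    # cluster statistics
    cluster_alpha: float = 0.05
    n_permutations: int = 1000
    adjacency_radius_m: float = 0.04
    # peak windows
    n1_window_ms: tuple[float, float] = (50.0, 150.0)
    p2_window_ms: tuple[float, float] = (150.0, 250.0)
    n400_window_ms: tuple[float, float] = (200.0, 1000.0)
    # ROIs
    roi_frontocentral: list[str] = field(
        default_factory=lambda: list(st.ROI_FRONTOCENTRAL)
    )
    roi_parietal: list[str] = field(default_factory=lambda: list(st.ROI_PARIETAL))
    # simulation overrides (scaled-down cohorts for demonstrations)
    simulation: dict = field(default_factory=dict)

    @property
    def lambda_grid(self) -> np.ndarray:
        lo, hi = self.lambda_grid_log2
        return 2.0 ** np.arange(lo, hi + 1)

    def lag_spec(self) -> trf_mod.LagSpec:
        return trf_mod.LagSpec(
            t_min_ms=self.lag_window_ms[0],
            t_max_ms=self.lag_window_ms[1],
            rate=self.analysis_rate,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in (
            "broadband_hz",
            "analysis_band_hz",
            "lag_window_ms",
            "lambda_grid_log2",
            "baseline_ms",
            "n1_window_ms",
            "p2_window_ms",
            "n400_window_ms",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# -- word-timing tables ----------------------------------------------------

_TIMING_COLUMNS = ["word", "onset", "offset", "pos", "surprisal", "altered"]


def read_word_timing(path: str | Path) -> list[Token]:
    """Read a word-timing TSV into validated, onset-sorted tokens.

    Expected header: ``word onset offset pos surprisal altered`` (onset and
    offset in seconds; blank surprisal means unannotated).  Malformed rows,
    non-monotone onsets and overlapping intervals raise errors naming the
    offending line number.
    """
    tokens: list[Token] = []
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if header[:3] != ["word", "onset", "offset"]:
        raise ValueError(f"{path}: line 1: expected header starting 'word onset offset'")
    col = {name: i for i, name in enumerate(header)}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            word = parts[col["word"]]
            onset = float(parts[col["onset"]])
            offset = float(parts[col["offset"]])
            pos = parts[col["pos"]] or None if "pos" in col and len(parts) > col["pos"] else None
            sval = (
                parts[col["surprisal"]]
                if "surprisal" in col and len(parts) > col["surprisal"]
                else ""
            )
            surp = float(sval) if sval.strip() else None
            aval = (
                parts[col["altered"]]
                if "altered" in col and len(parts) > col["altered"]
                else ""
            )
            altered = aval.strip().lower() in ("1", "true", "yes")
            tokens.append(
                Token(
                    text=word,
                    onset=onset,
                    offset=offset,
                    pos=pos,
                    surprisal=surp,
                    altered=altered,
                )
            )
        except (IndexError, ValueError) as err:
            raise ValueError(f"{path}: line {lineno}: {err}") from None
    try:
        validate_tokens(tokens)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from None
    return tokens


def write_word_timing(tokens: list[Token], path: str | Path) -> None:
    """Write tokens as TSV with 6-decimal timing precision (lossless round-trip)."""
    rows = []
    for t in tokens:
        rows.append(
            {
                "word": t.text,
                "onset": f"{t.onset:.6f}",
                "offset": f"{t.offset:.6f}",
                "pos": t.pos or "",
                "surprisal": "" if t.surprisal is None else f"{t.surprisal:.6f}",
                "altered": int(t.altered),
            }
        )
    pd.DataFrame(rows, columns=_TIMING_COLUMNS).rename(
        columns={"word": "word"}
    ).to_csv(path, sep="\t", index=False)


# -- pipeline orchestration ------------------------------------------------


def _group_lambda(
    cohort: dict, lags: trf_mod.LagSpec, grid: np.ndarray, features: list[str]
) -> tuple[float, np.ndarray]:
    """Group-level lambda: mean CV accuracy profile over subjects and
    conditions, maximized on the grid (smallest lambda on ties)."""
    profiles = []
    for subj in cohort["subjects"]:
        for epochs in subj["epochs"].values():
            cv = trf_mod.cross_validate_lambda(epochs, lags, grid, features)
            profiles.append(cv.mean_r)
    mean_profile = np.mean(profiles, axis=0)
    grid_sorted = np.sort(np.asarray(grid, dtype=float))
    return float(grid_sorted[int(np.argmax(mean_profile))]), mean_profile


def run_pipeline(config: PipelineConfig) -> dict:
    """Full analysis on a simulated cohort; returns and writes all results."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("semtrf")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage_marks: list[tuple[str, float]] = []

    def stage(name: str):
        logger.info("stage: %s", name)
        stage_marks.append((name, time.time()))

    try:
        stage("simulate")
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        sim_kwargs.setdefault("rate", config.analysis_rate)
        sim_kwargs.setdefault("trial_s", config.trial_s)
        sim_config = sim.SimulationConfig(**sim_kwargs)
        cohort = sim.simulate_cohort(sim_config)
        lags = trf_mod.LagSpec(
            t_min_ms=config.lag_window_ms[0],
            t_max_ms=config.lag_window_ms[1],
            rate=sim_config.rate,
        )
        grid = config.lambda_grid

        stage("lambda_selection")
        lam, profile = _group_lambda(cohort, lags, grid, trf_mod.FULL_FEATURES)
        logger.info("group-level lambda = %g", lam)

        stage("condition_trfs")
        trfs: dict[str, dict[str, trf_mod.TRFModel]] = {}
        for subj in cohort["subjects"]:
            trfs[subj["subject"]] = {
                cond: trf_mod.condition_trf(
                    epochs, lam, lags, trf_mod.FULL_FEATURES,
                    baseline_window_ms=config.baseline_ms,
                )
                for cond, epochs in subj["epochs"].items()
            }

        stage("added_value")
        delta_rows = []
        for subj in cohort["subjects"]:
            res = trf_mod.added_value(subj["epochs"], lags, grid)
            delta_rows.append(
                {"subject": subj["subject"], "group": subj["group"], **res}
            )
        delta_df = pd.DataFrame(delta_rows)
        wil = st.wilcoxon_signed_rank(delta_df["delta_r"].to_numpy(), "greater")
        delta_df.to_csv(out_dir / "added_value.tsv", sep="\t", index=False)

        stage("cluster_tests")
        ch_names = cohort["subjects"][0]["epochs"]["Control"].ch_names
        from .preprocess import standard_positions

        positions = standard_positions(ch_names)
        adjacency = cl.build_adjacency(ch_names, positions, config.adjacency_radius_m)
        f_surp = trf_mod.FULL_FEATURES.index("word_surprisal")
        cluster_results = {}
        for group in ("NH", "CI"):
            subjects = [s for s in cohort["subjects"] if s["group"] == group]
            A = np.stack(
                [trfs[s["subject"]]["E45"].weights[f_surp].T for s in subjects]
            )
            B = np.stack(
                [trfs[s["subject"]]["Control"].weights[f_surp].T for s in subjects]
            )
            res = cl.cluster_perm_test(
                A,
                B,
                "paired",
                adjacency,
                cluster_alpha=config.cluster_alpha,
                n_permutations=config.n_permutations,
                seed=config.seed + 1,
            )
            cluster_results[group] = res
            cl.result_to_json(
                res, ch_names, lags.times_ms, out_dir / f"clusters_{group}.json"
            )
            cl.summary_table(res, ch_names, lags.times_ms).to_csv(
                out_dir / f"clusters_{group}.tsv", sep="\t", index=False
            )

        stage("peaks")
        roi_fc = [c for c in config.roi_frontocentral if c in ch_names]
        roi_par = [c for c in config.roi_parietal if c in ch_names]
        peak_rows = []
        for subj in cohort["subjects"]:
            sid = subj["subject"]
            env_waves = [
                st.roi_waveform(trfs[sid][cond], "envelope", roi_fc)[1]
                for cond in ("Control", "E45")
            ]
            times = trfs[sid]["Control"].times_ms
            peaks = st.extract_sensory_peaks(
                np.mean(env_waves, axis=0), times,
                config.n1_window_ms, config.p2_window_ms,
            )
            n400 = st.extract_n400(
                trfs[sid]["E45"], trfs[sid]["Control"], roi_par,
                window_ms=config.n400_window_ms,
            )
            peak_rows.append(
                {
                    "subject": sid,
                    "group": subj["group"],
                    "n1_latency_ms": peaks["N1"].latency_ms,
                    "n1_amplitude": peaks["N1"].amplitude,
                    "p2_latency_ms": peaks["P2"].latency_ms,
                    "p2_amplitude": peaks["P2"].amplitude,
                    "n1p2_amplitude": peaks["n1p2"],
                    "n400_latency_ms": n400.latency_ms,
                    "n400_amplitude": n400.amplitude,
                }
            )
        peaks_df = pd.DataFrame(peak_rows)
        peaks_df.to_csv(out_dir / "peaks.tsv", sep="\t", index=False)

        stage("group_stats")
        nh = peaks_df[peaks_df["group"] == "NH"]
        ci = peaks_df[peaks_df["group"] == "CI"]
        tests = {
            "n1_latency": st.welch_t(nh["n1_latency_ms"], ci["n1_latency_ms"]),
            "p2_latency": st.welch_t(nh["p2_latency_ms"], ci["p2_latency_ms"]),
            "n1p2_amplitude": st.welch_t(nh["n1p2_amplitude"], ci["n1p2_amplitude"]),
            "n400_latency": st.welch_t(nh["n400_latency_ms"], ci["n400_latency_ms"]),
            "n400_amplitude": st.welch_t(nh["n400_amplitude"], ci["n400_amplitude"]),
            "added_value_wilcoxon": wil,
        }
        behavior = cohort["behavior"]
        merged = behavior.merge(peaks_df, on=["subject", "group"])
        for col in ("judgment_pct", "recall_pct"):
            tests[f"{col}_group"] = st.welch_t(
                merged.loc[merged["group"] == "NH", col],
                merged.loc[merged["group"] == "CI", col],
            )
        stat_rows = [
            {
                "test": name,
                "statistic": r.statistic,
                "df": r.df,
                "p": r.p,
                "effect": r.effect,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
            }
            for name, r in tests.items()
        ]
        pd.DataFrame(stat_rows).to_csv(out_dir / "group_stats.tsv", sep="\t", index=False)

        stage("correlations")
        corr_tables = {}
        for group in ("NH", "CI"):
            sub = merged[merged["group"] == group]
            if len(sub) < 5:
                logger.warning(
                    "group %s has %d subjects; skipping correlations", group, len(sub)
                )
                continue
            pairs = [
                (
                    f"{group}:judgment_vs_n400_amplitude",
                    sub["judgment_pct"].to_numpy(),
                    sub["n400_amplitude"].to_numpy(),
                ),
                (
                    f"{group}:recall_vs_n400_amplitude",
                    sub["recall_pct"].to_numpy(),
                    sub["n400_amplitude"].to_numpy(),
                ),
                (
                    f"{group}:judgment_vs_n400_latency",
                    sub["judgment_pct"].to_numpy(),
                    sub["n400_latency_ms"].to_numpy(),
                ),
                (
                    f"{group}:recall_vs_n400_latency",
                    sub["recall_pct"].to_numpy(),
                    sub["n400_latency_ms"].to_numpy(),
                ),
            ]
            usable = []
            for name, x, y in pairs:
                ok = np.isfinite(np.asarray(x, float)) & np.isfinite(np.asarray(y, float))
                if len(set(np.asarray(x)[ok])) < 2 or len(set(np.asarray(y)[ok])) < 2:
                    logger.warning("skipping degenerate correlation pair %s", name)
                    continue
                usable.append((name, x, y))
            if usable:
                corr_tables[group] = st.spearman_fdr(usable)
        corr_df = (
            pd.concat(corr_tables.values(), ignore_index=True)
            if corr_tables
            else pd.DataFrame(columns=["pair", "n", "rho", "p", "q"])
        )
        corr_df.to_csv(out_dir / "correlations.tsv", sep="\t", index=False)
        behavior.to_csv(out_dir / "behavior.tsv", sep="\t", index=False)

        stage("provenance")
        marks = stage_marks + [("end", time.time())]
        provenance = {
            "config_digest": config.digest(),
            "seed": config.seed,
            "lambda": lam,
            "stages_s": {
                name: round(marks[i + 1][1] - t, 3)
                for i, (name, t) in enumerate(stage_marks)
            },
            "versions": _versions(),
        }
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))
        config.to_yaml(out_dir / "config.yaml")

        return {
            "lambda": lam,
            "lambda_profile": profile,
            "delta_r": delta_df,
            "wilcoxon": wil,
            "clusters": cluster_results,
            "peaks": peaks_df,
            "tests": tests,
            "correlations": corr_df,
            "behavior": behavior,
            "elapsed_s": time.time() - t0,
        }
    finally:
        root.removeHandler(handler)
        handler.close()


def _versions() -> dict:
    import numpy
    import pandas
    import scipy

    from . import __version__

    return {
        "semtrf": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
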