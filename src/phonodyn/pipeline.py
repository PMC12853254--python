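"""End-to-end orchestration of the synthetic phoneme-decoding workflow.

`run_all` composes the full chain — lexicon → utterance → annotation →
per-subject simulation → preprocessing → TG decoding → metrics → group
statistics — and writes a deterministic output tree with machine-readable
JSON summaries.  The intermediate helpers (`simulate_session`,
`subject_tg`) are the building blocks scripts and tests reuse to run
partial experiments.

Conventions, binding everywhere: times are seconds relative to recording
start (events) or phoneme onset (epochs); intervals are half-open
[start, end) in sample space; sample indices are 0-based.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .annotate import FeatureTable, annotate_events, load_feature_map
from .decode import DecodeConfig, TGMatrix, decode_all_features, decode_per_sensor, tg_decode_subsets
from .lexicon import DEFAULT_DURATION_MODEL, Lexicon, generate_lexicon, sample_utterance
from .preprocess import preprocess_chain
from .simulate import GroundTruth, SimConfig, make_ground_truth, simulate_subject, subject_seed
from .stats import TestConfig, delaunay_adjacency, max_t_sensor_test, one_sample_cluster_perm, perm_ttest_scalar, two_sample_cluster_perm
from .tgmetrics import diagonal, dynamic_delta, generalization_width, halfmax_width, reorient

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# configuration


@dataclass
class SessionConfig:
    """Stimulus-side settings shared by all subjects (one 'story')."""

    n_words: int = 600
    lexicon_words: int = 2000
    word_length_range: tuple[int, int] = (2, 7)
    zipf_exponent: float = 1.0
    duration_model: tuple[float, float, float] = DEFAULT_DURATION_MODEL
    phonotactics: str = "cv"  # 'cv' natural-like, 'iid' controlled stimulus


@dataclass
class PreprocConfig:
    """Conditioning-chain settings applied before epoching.

    The high-pass stage exists to remove electrode drift and slow artifacts
    in real recordings; the synthetic noise model is stationary and
    zero-mean by construction, so the default here is no high-pass (its
    multi-second impulse response would otherwise smear each response's DC
    content far outside the encoding window).  For real data pass
    ``highpass=(0.5, 0.45, 2000)``.
    """

    highpass: tuple[float, float, int] | None = None
    lowpass: tuple[float, float, int] | None = (25.0, 27.5, 2000)
    window: tuple[float, float] = (-0.2, 0.6)


@dataclass
class MetricsConfig:
    train_window: tuple[float, float] = (0.0, 0.35)
    width_mode: str = "timecourse-sd"
    ci_level: float = 0.95


@dataclass
class PipelineConfig:
    """Resolved configuration for a full run; unknown YAML keys rejected."""

    seed: int = 0
    out_dir: str = "phonodyn_out"
    groups: tuple[str, ...] = ("control", "aphasia")
    session: SessionConfig = field(default_factory=SessionConfig)
    simulate: SimConfig = field(default_factory=SimConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    decode: DecodeConfig = field(default_factory=DecodeConfig)
    stats: TestConfig = field(default_factory=TestConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    decode_features: tuple[str, ...] | None = None  # None: all retained
    entropy_subsets: bool = False
    per_sensor: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, d: dict):
            allowed = {f.name for f in fields(klass)}
            unknown = set(d) - allowed
            if unknown:
                raise ValueError(
                    f"unknown config keys for {klass.__name__}: {sorted(unknown)}"
                )
            return d

        sections = {
            "session": SessionConfig,
            "simulate": SimConfig,
            "preproc": PreprocConfig,
            "decode": DecodeConfig,
            "stats": TestConfig,
            "metrics": MetricsConfig,
        }
        kwargs = dict(build(cls, raw))
        for name, klass in sections.items():
            if name in kwargs:
                kwargs[name] = klass(**build(klass, kwargs[name]))
        for tup_key in ("groups", "decode_features"):
            if kwargs.get(tup_key) is not None:
                kwargs[tup_key] = tuple(kwargs[tup_key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where results land must not change what they are
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# workflow building blocks


def simulate_session(
    cfg: PipelineConfig,
) -> tuple[Lexicon, pd.DataFrame, FeatureTable]:
    """Build the shared stimulus: lexicon, annotated events, feature table."""
    sess = cfg.session
    lex = generate_lexicon(
        sess.lexicon_words,
        length_range=sess.word_length_range,
        zipf_exponent=sess.zipf_exponent,
        seed=cfg.seed,
        phonotactics=sess.phonotactics,
    )
    events = sample_utterance(
        lex, sess.n_words, sess.duration_model, seed=cfg.seed + 1
    )
    events, table = annotate_events(events, lex)
    return lex, events, table


def signal_feature_names(cfg: PipelineConfig, table: FeatureTable) -> tuple[str, ...]:
    if cfg.decode_features is not None:
        missing = [f for f in cfg.decode_features if f not in table.feature_names]
        if missing:
            raise ValueError(f"requested features not retained: {missing}")
        return tuple(cfg.decode_features)
    return tuple(table.feature_names)


def subject_tg(
    events: pd.DataFrame,
    table: FeatureTable,
    truth: GroundTruth,
    cfg: PipelineConfig,
    group: str,
    subject_index: int,
    subset_column: str | None = None,
    need_overall: bool = True,
) -> dict:
    """Simulate one subject and decode: returns TG average (and subsets).

    The returned dict has keys ``avg`` (feature-average TGMatrix),
    ``per_feature``, ``epochs``, ``truth`` and, when ``subset_column`` is
    given, ``subsets`` mapping level → feature-average TGMatrix.  Pass
    ``need_overall=False`` with a subset column to skip the whole-set
    decoding when only the subset matrices are needed.
    """
    seed = subject_seed(cfg.seed, group, subject_index)
    sim = replace(cfg.simulate, seed=cfg.seed)
    eeg, truth_r = simulate_subject(events, table, truth, sim, group, seed)
    epochs = preprocess_chain(
        eeg,
        events,
        target_hz=sim.sampling_rate_hz,
        highpass=cfg.preproc.highpass,
        lowpass=cfg.preproc.lowpass,
        window=cfg.preproc.window,
    )
    feats = [f for f in signal_feature_names(cfg, table) if f in truth.patterns]
    rows = epochs.events["source_row"].to_numpy()
    sub_table = FeatureTable(
        table.matrix[rows][:, [table.feature_names.index(f) for f in feats]],
        tuple(feats),
    )
    dec = replace(cfg.decode, seed=subject_seed(cfg.seed, group + "-dec", subject_index))
    out: dict = {"epochs": epochs, "truth": truth_r}
    if need_overall or subset_column is None:
        per_feature, avg = decode_all_features(
            epochs, sub_table, dec, subject=f"{group}{subject_index}"
        )
        out.update({"avg": avg, "per_feature": per_feature})
    if subset_column is not None:
        subset_labels = epochs.events[subset_column].to_numpy()
        per_level: dict[str, list[TGMatrix]] = {}
        for f in feats:
            y = sub_table.column(f)
            mats = tg_decode_subsets(epochs, y, subset_labels, dec, feature=f)
            for lev, m in mats.items():
                per_level.setdefault(lev, []).append(m)
        out["subsets"] = {
            lev: replace(ms[0], values=np.mean([m.values for m in ms], axis=0),
                         feature="average")
            for lev, ms in per_level.items()
        }
    return out


# --------------------------------------------------------------------------
# run-all


def _cluster_windows(result, times, alpha=0.05):
    mask = result.significant_mask(alpha)
    wins = []
    idx = np.flatnonzero(mask)
    if idx.size:
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        wins = [[float(times[s[0]]), float(times[s[-1]])] for s in splits]
    return wins


def run_all(config: PipelineConfig | str | Path) -> Path:
    """Execute the full synthetic workflow and write the output tree.

    Tree: ``events/``, ``tg/``, ``metrics/``, ``stats/``, ``report/`` under
    ``config.out_dir``; ``report/summary.json`` holds the figure-level
    numbers (above-chance diagonal windows, group clusters, widths per
    group, entropy/subset analyses, optional sensor test).  Deterministic
    given (config, seed).
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(config.out_dir)
    for sub in ("events", "tg", "metrics", "stats", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    (out / "config_resolved.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )

    stage = "simulate-session"
    try:
        lex, events, table = simulate_session(config)
        lex.to_tsv(out / "events" / "lexicon.tsv")
        annotated = events.copy()
        for j, name in enumerate(table.feature_names):
            annotated[f"feat_{name}"] = table.matrix[:, j]
        pio.write_events_tsv(annotated, out / "events" / "events.tsv")

        feats = signal_feature_names(config, table)
        sim = replace(config.simulate, signal_features=feats)
        config = replace(config, simulate=sim)
        truth = make_ground_truth(feats, sim, seed=config.seed)
        pio.write_ground_truth(truth, out / "events" / "ground_truth.json")

        stage = "decode"
        subset_col = "entropy_tertile" if config.entropy_subsets else None
        results: dict[str, list[dict]] = {}
        for group in config.groups:
            results[group] = []
            for si in range(sim.n_subjects_per_group):
                res = subject_tg(events, table, truth, config, group, si, subset_col)
                results[group].append(res)
                np.save(out / "tg" / f"tg_{group}{si}.npy", res["avg"].values)
        (out / "tg" / "manifest.json").write_text(
            json.dumps(
                {
                    "features": list(feats),
                    "subsets": ["low", "high"] if subset_col else ["all"],
                    "groups": list(config.groups),
                    "n_subjects_per_group": sim.n_subjects_per_group,
                    "config_hash": config.config_hash(),
                }
            )
        )

        stage = "metrics"
        times = results[config.groups[0]][0]["avg"].train_times_s
        diags = {
            g: np.stack([diagonal(r["avg"]) for r in results[g]])
            for g in config.groups
        }
        widths = {}
        for g in config.groups:
            widths[g] = []
            for r in results[g]:
                prof = reorient(r["avg"], config.metrics.train_window)
                widths[g].append(
                    {
                        "width_ci_s": generalization_width(
                            prof, config.metrics.ci_level, config.metrics.width_mode
                        ),
                        "width_halfmax_s": halfmax_width(prof),
                    }
                )
        pd.DataFrame(
            [
                {"group": g, "subject": i, **w}
                for g in widths
                for i, w in enumerate(widths[g])
            ]
        ).to_csv(out / "metrics" / "widths.tsv", sep="\t", index=False)

        stage = "stats"
        stats_cfg = config.stats
        summary: dict = {
            "provenance": {
                "package_version": __import__("phonodyn").__version__,
                "config_hash": config.config_hash(),
                "seed": config.seed,
            },
            "n_events": int(len(events)),
            "diagonal_windows": {},
            "dynamic_delta_clusters": {},
            "widths": {
                g: {
                    "ci": [w["width_ci_s"] for w in widths[g]],
                    "halfmax": [w["width_halfmax_s"] for w in widths[g]],
                }
                for g in config.groups
            },
        }
        for g in config.groups:
            res = one_sample_cluster_perm(diags[g], 0.5, stats_cfg)
            summary["diagonal_windows"][g] = _cluster_windows(res, times, stats_cfg.alpha)
            deltas = np.stack([dynamic_delta(r["avg"]) for r in results[g]])
            dres = one_sample_cluster_perm(deltas, 0.0, stats_cfg)
            neg = [
                {"window": [float(times[c[0]]), float(times[c[-1]])], "p": float(p)}
                for c, m, p in zip(dres.clusters, dres.masses, dres.p_values)
                if m < 0
            ]
            summary["dynamic_delta_clusters"][g] = neg
        if len(config.groups) == 2:
            g1, g2 = config.groups
            gres = two_sample_cluster_perm(diags[g1], diags[g2], stats_cfg)
            summary["group_clusters"] = [
                {
                    "window": [float(times[c[0]]), float(times[c[-1]])],
                    "mass": float(m),
                    "p": float(p),
                }
                for c, m, p in zip(gres.clusters, gres.masses, gres.p_values)
            ]
            wa = [w["width_ci_s"] for w in widths[g1]]
            wb = [w["width_ci_s"] for w in widths[g2]]
            t_w, p_w = perm_ttest_scalar(
                wa, wb, min(stats_cfg.n_permutations, 10_000), stats_cfg.seed
            )
            summary["width_comparison"] = {"t": t_w, "p": p_w}
        if config.entropy_subsets:
            ent: dict = {}
            for g in config.groups:
                ent[g] = {}
                for lev in ("low", "high"):
                    tcs = [
                        diagonal(r["subsets"][lev])
                        for r in results[g]
                        if lev in r.get("subsets", {})
                    ]
                    if tcs:
                        ent[g][lev] = np.stack(tcs)
            summary["entropy"] = {
                g: {lev: arr.mean(axis=0).tolist() for lev, arr in ent[g].items()}
                for g in ent
            }
        if config.per_sensor and len(config.groups) == 2:
            stage = "sensor"
            topo = {}
            for g in config.groups:
                rowset = []
                for si, r in enumerate(results[g]):
                    rows = r["epochs"].events["source_row"].to_numpy()
                    sub_table = FeatureTable(
                        table.matrix[rows][
                            :, [table.feature_names.index(f) for f in feats]
                        ],
                        tuple(feats),
                    )
                    rowset.append(decode_per_sensor(r["epochs"], sub_table, config.decode))
                topo[g] = np.stack(rowset)
            adj = delaunay_adjacency(results[config.groups[0]][0]["epochs"].ch_pos)
            scfg = replace(stats_cfg, adjacency=adj)
            mres = max_t_sensor_test(topo[config.groups[0]], topo[config.groups[1]], scfg)
            summary["sensor_test"] = {
                "t": mres.t.tolist(),
                "p_corrected": mres.p_corrected.tolist(),
                "significant": mres.significant.tolist(),
            }
        (out / "stats" / "summary.json").write_text(json.dumps(summary, indent=2))
        (out / "report" / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (config at "
            f"{out / 'config_resolved.yaml'}): {err}"
        ) from err
    return out / "report" / "summary.json"


# --------------------------------------------------------------------------
# validation


def validate_events(path: str | Path, inventory: set[str] | None = None) -> list[str]:
    """Check an events TSV: monotone onsets, positive durations, contiguous
    words, known phonemes.  Returns a list of error strings (empty = valid).
    """
    errors: list[str] = []
    try:
        ev = pio.read_events_tsv(path)
    except Exception as err:  # unreadable or malformed
        return [f"unreadable events file: {err}"]
    if inventory is None:
        inventory = set(load_feature_map())
    onsets = ev["onset_s"].to_numpy()
    bad = np.flatnonzero(np.diff(onsets) < 0)
    for i in bad:
        errors.append(f"row {i + 1}: onset regression ({onsets[i + 1]} < {onsets[i]})")
    nonpos = np.flatnonzero(ev["duration_s"].to_numpy() <= 0)
    for i in nonpos:
        errors.append(f"row {i}: non-positive duration")
    wi = ev["word_index"].to_numpy()
    if (np.diff(wi) < 0).any() or (np.diff(wi) > 1).any():
        rows = np.flatnonzero((np.diff(wi) < 0) | (np.diff(wi) > 1))
        for i in rows:
            errors.append(f"row {i + 1}: word_index not contiguous")
    unknown = sorted(set(ev["phoneme"]) - inventory)
    if unknown:
        errors.append(f"unknown phonemes: {unknown}")
    return errors
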