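"""End-to-end orchestration: simulate -> preprocess -> GC -> network ->
metrics -> compare, with a single plain-text configuration object.

One master seed expands deterministically into per-subject and per-stage
seeds, so a config file plus one integer reproduces every number the
pipeline emits, byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import warnings

from .compare import StateComparison, change_rate, compare_states, summarize_states
from .granger import GCMatrix, gc_matrix
from .io import write_gc_matrix, write_network
from .metrics import network_metrics
from .network import DirectedNetwork, ThresholdSelection, build_network, default_grid, select_threshold
from .preprocessing import (
    bandpass,
    mark_artifacts,
    rereference_common_average,
    segment_random,
    slice_windows,
)
from .recording import BandDefinition, Recording
from .report import save_comparison_table
from .synthetic import StateSpec, default_scenario, derive_seed, generate_scenario, scale_edges_incident, _frontal_central

__all__ = ["PipelineConfig", "PipelineResult", "analyze_recording", "run_pipeline"]

METRIC_COLUMNS = [
    "mean_total_degree",
    "char_path_length",
    "mean_clustering",
    "global_efficiency",
]


@dataclass
class PipelineConfig:
    """All tunable settings of the study pipeline, with the study defaults.

    Frequency bands are mu (8-13 Hz) and beta (13-30 Hz); the broadband
    pre-filter is 0.5-45 Hz; artifacts are samples beyond 50 uV; five 10-s
    segments are drawn per state; the AR order is chosen by BIC; the network
    threshold defaults to the integrity rule (no isolated nodes) on the
    pooled per-band mean GC matrix.
    """

    bands: dict = field(default_factory=lambda: {"mu": [8.0, 13.0], "beta": [13.0, 30.0]})
    broadband: tuple = (0.5, 45.0)
    filter_order: int = 4  # band-split (mu/beta) filters
    broadband_filter_order: int = 12  # steep enough to kill 50 Hz line noise
    artifact_threshold_uv: float = 50.0
    artifact_guard_s: float = 0.2
    n_segments: int = 5
    segment_duration_s: float = 10.0
    ar_order: object = 5  # fixed lag order, or "auto" for per-recording BIC
    ar_order_max: int = 20
    threshold_policy: str = "integrity"  # or "fixed"
    fixed_thresholds: dict = field(default_factory=lambda: {"mu": 0.0650, "beta": 0.0750})
    max_isolated_fraction: float = 0.0
    threshold_grid_size: int = 100
    state_scales: dict = field(
        default_factory=lambda: {"rest_before": 1.0, "task": 0.4, "rest_after": 0.7}
    )
    n_subjects: int = 16
    n_channels: int = 8
    sample_rate: float = 1000.0
    state_duration_s: float = 60.0
    coupling_weight: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, edges in self.bands.items():
            low, high = edges
            BandDefinition(name, low, high).validate_against_rate(self.sample_rate)
        unknown = set(self.fixed_thresholds) - set(self.bands)
        if unknown:
            raise ValueError(f"fixed_thresholds reference unknown band(s): {sorted(unknown)}")
        if self.threshold_policy not in ("integrity", "fixed"):
            raise ValueError(f"unknown threshold_policy '{self.threshold_policy}'")
        if self.threshold_policy == "fixed":
            missing = set(self.bands) - set(self.fixed_thresholds)
            if missing:
                raise ValueError(f"no fixed threshold for band(s): {sorted(missing)}")
        if self.ar_order != "auto" and (not isinstance(self.ar_order, int) or self.ar_order < 1):
            raise ValueError("ar_order must be 'auto' or a positive integer")
        if len(self.state_scales) < 2:
            raise ValueError("need at least two states to compare")
        if self.n_subjects < 1 or self.n_channels < 2:
            raise ValueError("need >= 1 subject and >= 2 channels")

    def band_definitions(self) -> dict[str, BandDefinition]:
        return {name: BandDefinition(name, *edges) for name, edges in self.bands.items()}

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["broadband"] = list(d["broadband"])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if isinstance(source, Path) or "\n" not in str(source) else str(source)
        d = yaml.safe_load(text)
        d["broadband"] = tuple(d["broadband"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus the provenance to regenerate it."""

    config: PipelineConfig
    metrics_table: pd.DataFrame  # one row per subject x state x band
    node_table: pd.DataFrame  # per-node degrees, for topographic maps
    summaries: pd.DataFrame
    comparisons: list[StateComparison]
    thresholds: dict[str, float]
    threshold_selections: dict[str, ThresholdSelection]
    gc_matrices: dict[tuple[int, str, str], GCMatrix]  # (subject, state, band)
    networks: dict[tuple[int, str, str], DirectedNetwork]

    def comparison(self, band: str, metric: str, state_b: str) -> StateComparison:
        """Look up one comparison (reference state vs ``state_b``)."""
        key = f"{band}:{metric}"
        for c in self.comparisons:
            if c.metric_name == key and c.state_pair[1] == state_b:
                return c
        raise KeyError(f"no comparison {key} vs {state_b}")


def analyze_recording(
    rec: Recording,
    config: PipelineConfig,
    seed: int,
) -> dict[str, GCMatrix]:
    """Preprocess one recording and estimate the per-band mean GC matrices.

    Fixed stage order: broadband filter -> common-average re-reference ->
    artifact mask -> band split -> shared random segmentation -> per-segment
    GCI, averaged. Both bands use identical window positions.
    """
    broad = bandpass(rec, *config.broadband, order=config.broadband_filter_order)
    reref = rereference_common_average(broad)
    mask = mark_artifacts(reref, config.artifact_threshold_uv, config.artifact_guard_s)
    base_segs = segment_random(
        reref, mask, config.n_segments, config.segment_duration_s, seed
    )
    window = int(round(config.segment_duration_s * rec.sample_rate))
    out: dict[str, GCMatrix] = {}
    for name, band in config.band_definitions().items():
        band_rec = bandpass(reref, band.low_hz, band.high_hz, order=config.filter_order)
        segs = slice_windows(band_rec, base_segs.window_starts, window, band=band, seed=seed)
        out[name] = gc_matrix(segs, p=config.ar_order, p_max=config.ar_order_max)
    return out


def _scenario_for_subject(config: PipelineConfig, subject: int):
    base = default_scenario(
        n_channels=config.n_channels,
        sample_rate=config.sample_rate,
        duration_s=config.state_duration_s,
        seed=derive_seed(config.seed, subject),
        coupling_weight=config.coupling_weight,
    )
    targets = _frontal_central(base.base.coupling.node_labels)
    states = tuple(
        StateSpec(
            name,
            config.state_duration_s,
            scale_edges_incident(base.base.coupling, targets, scale) if scale != 1.0 else (),
        )
        for name, scale in config.state_scales.items()
    )
    return type(base)(base=base.base, states=states)


def run_pipeline(
    config: PipelineConfig,
    recordings: dict[int, list[tuple[str, Recording]]] | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full study and (optionally) write every stage's outputs.

    ``recordings`` maps subject id to (state, Recording) pairs; when omitted,
    the default synthetic scenario generates one session per subject from
    seeds derived from the master seed.
    """
    config.validate()
    if recordings is None:
        recordings = {
            s: generate_scenario(_scenario_for_subject(config, s))
            for s in range(config.n_subjects)
        }

    band_defs = config.band_definitions()
    gcs: dict[tuple[int, str, str], GCMatrix] = {}
    log_lines = [f"config_hash={config.config_hash()}", f"master_seed={config.seed}"]
    for subject, states in recordings.items():
        for k, (state, rec) in enumerate(states):
            seg_seed = derive_seed(config.seed, subject, k, 1)
            per_band = analyze_recording(rec, config, seg_seed)
            for band_name, gc in per_band.items():
                gcs[(subject, state, band_name)] = gc
                log_lines.append(
                    f"subject={subject} state={state} band={band_name} "
                    f"segment_seed={seg_seed} ar_order={gc.order_used}"
                )

    # One threshold per band, applied to every subject and state.
    state_names = list(dict.fromkeys(state for states in recordings.values() for state, _ in states))
    thresholds: dict[str, float] = {}
    selections: dict[str, ThresholdSelection] = {}
    for band_name, band in band_defs.items():
        if config.threshold_policy == "fixed":
            thresholds[band_name] = float(config.fixed_thresholds[band_name])
            selections[band_name] = ThresholdSelection(thresholds[band_name], True)
        else:
            # One threshold per band, chosen so that EVERY state's
            # across-subject mean network keeps its integrity: the largest
            # grid value feasible for each state-mean matrix, minimised over
            # states (isolation is monotone in the threshold).
            labels = next(iter(gcs.values())).channel_labels
            state_means = [
                GCMatrix(
                    values=np.mean(
                        [gc.values for (s, st, b), gc in gcs.items() if b == band_name and st == state],
                        axis=0,
                    ),
                    channel_labels=labels,
                    order_used=0,
                    band=band,
                    n_segments_averaged=1,
                )
                for state in state_names
            ]
            lo = min(float(m.offdiagonal().min()) for m in state_means)
            hi = max(float(m.offdiagonal().max()) for m in state_means)
            grid = np.linspace(lo, hi, config.threshold_grid_size)
            sels = [
                select_threshold(m, config.max_isolated_fraction, grid)
                for m in state_means
            ]
            sel = min(sels, key=lambda s: s.threshold)
            sel = ThresholdSelection(sel.threshold, all(s.feasible for s in sels))
            thresholds[band_name] = sel.threshold
            selections[band_name] = sel
        log_lines.append(
            f"band={band_name} threshold={thresholds[band_name]:.17g} "
            f"policy={config.threshold_policy} feasible={selections[band_name].feasible}"
        )

    networks: dict[tuple[int, str, str], DirectedNetwork] = {}
    metric_rows = []
    node_rows = []
    for (subject, state, band_name), gc in gcs.items():
        net = build_network(gc, thresholds[band_name])
        networks[(subject, state, band_name)] = net
        m = network_metrics(net)
        metric_rows.append(
            {
                "subject": subject,
                "state": state,
                "band": band_name,
                "mean_total_degree": float(m.total_degree.mean()),
                "char_path_length": m.char_path_length,
                "mean_clustering": m.mean_clustering,
                "global_efficiency": m.global_efficiency,
                "n_edges": net.n_edges,
                "n_unreachable_pairs": m.n_unreachable_pairs,
                "threshold": thresholds[band_name],
                "ar_order": gc.order_used,
            }
        )
        for i, lab in enumerate(net.node_labels):
            node_rows.append(
                {
                    "subject": subject,
                    "state": state,
                    "band": band_name,
                    "channel": lab,
                    "in_degree": int(m.in_degree[i]),
                    "out_degree": int(m.out_degree[i]),
                    "total_degree": int(m.total_degree[i]),
                    "clustering": float(m.node_clustering[i]),
                }
            )
    metrics_table = pd.DataFrame(metric_rows)
    node_table = pd.DataFrame(node_rows)

    summaries = pd.concat(
        [
            summarize_states(grp, METRIC_COLUMNS).assign(band=band_name)
            for band_name, grp in metrics_table.groupby("band", sort=False)
        ],
        ignore_index=True,
    )

    reference = state_names[0]
    comparisons: list[StateComparison] = []
    for band_name in band_defs:
        band_table = metrics_table[metrics_table["band"] == band_name]
        for metric in METRIC_COLUMNS:
            for other in state_names[1:]:
                try:
                    c = compare_states(band_table, metric, reference, other)
                except ValueError as err:
                    # A degenerate paired test (e.g. zero-variance
                    # differences at tiny subject counts) should not abort
                    # the study; the comparison is reported as undefined.
                    warnings.warn(
                        f"{band_name}:{metric} {reference} vs {other}: {err}",
                        stacklevel=2,
                    )
                    sub = band_table.pivot_table(
                        index="subject", columns="state", values=metric,
                        aggfunc="first", dropna=False,
                    )
                    a = sub[reference].dropna()
                    b = sub[other].dropna()
                    c = StateComparison(
                        metric_name=metric,
                        state_pair=(reference, other),
                        n_subjects=int(min(len(a), len(b))),
                        mean_a=float(a.mean()),
                        mean_b=float(b.mean()),
                        t_statistic=float("nan"),
                        p_value=float("nan"),
                        mean_change_rate=change_rate(float(a.mean()), float(b.mean())),
                    )
                c.metric_name = f"{band_name}:{metric}"
                comparisons.append(c)

    result = PipelineResult(
        config=config,
        metrics_table=metrics_table,
        node_table=node_table,
        summaries=summaries,
        comparisons=comparisons,
        thresholds=thresholds,
        threshold_selections=selections,
        gc_matrices=gcs,
        networks=networks,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir), log_lines)
    return result


def _write_outputs(result: PipelineResult, outdir: Path, log_lines: list[str]) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(outdir / "config.yaml")
    result.metrics_table.to_csv(outdir / "metrics.csv", index=False, float_format="%.17g")
    result.node_table.to_csv(outdir / "node_metrics.csv", index=False, float_format="%.17g")
    result.summaries.to_csv(outdir / "summaries.csv", index=False, float_format="%.17g")
    save_comparison_table(result.comparisons, outdir / "comparisons.csv")
    comp_json = {
        f"{c.metric_name}|{c.state_pair[0]}->{c.state_pair[1]}": {
            "t": c.t_statistic,
            "p": c.p_value,
            "change_rate_pct": c.mean_change_rate,
            "n": c.n_subjects,
        }
        for c in result.comparisons
    }
    (outdir / "comparisons.json").write_text(json.dumps(comp_json, indent=2, sort_keys=True))
    (outdir / "thresholds.json").write_text(
        json.dumps(
            {
                b: {"threshold": t, "feasible": result.threshold_selections[b].feasible}
                for b, t in result.thresholds.items()
            },
            indent=2,
            sort_keys=True,
        )
    )
    # Mean GC matrix and an example network per state x band.
    gc_dir = outdir / "gc"
    gc_dir.mkdir(exist_ok=True)
    keys = sorted(result.gc_matrices, key=str)
    combos = sorted({(st, b) for _, st, b in keys})
    for st, b in combos:
        mats = [result.gc_matrices[k].values for k in keys if k[1] == st and k[2] == b]
        ref = result.gc_matrices[keys[0]]
        mean_gc = GCMatrix(
            values=np.mean(mats, axis=0),
            channel_labels=ref.channel_labels,
            order_used=ref.order_used,
            band=None,
            n_segments_averaged=len(mats),
        )
        write_gc_matrix(mean_gc, gc_dir / f"mean_gc_{st}_{b}.csv", extra={"state": st, "band_name": b})
        net = build_network(mean_gc, result.thresholds[b])
        write_network(net, gc_dir / f"mean_network_{st}_{b}")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
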