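"""Run configuration and the one-shot pipeline runner.

``run_pipeline`` chains preprocessing, tuning, state-space geometry,
selectivity permutation tests and population decoding on one session
(either simulated from a named experiment or loaded from files), writes
tidy per-stage tables plus a JSON summary into the output directory, and
logs every seed and decided default.  All randomness flows from the named
seeds in the configuration; rerunning with the same configuration
regenerates every numeric output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from . import synthetic_data as synth
from .decoding import build_trial_vectors, label_permutation_test
from .errors import ConfigError, PipelineError
from .population_geometry import cluster_stimuli, interstate_distance, project_state_space
from .selectivity_permutation import selectivity_tests
from .trace_processing import compute_dff, detect_responders, extract_trial_peaks
from .tuning_profile import (
    build_tuning_profile,
    discriminative_class,
    venn_categorize,
)

logger = logging.getLogger("s1pop")

EXPERIMENTS = {
    "three_stimulus": (synth.three_stimulus_population, synth.THREE_STIMULI),
    "texture_dynamics": (synth.texture_dynamics_population, synth.TEXTURE_DYNAMICS),
    "graded_pinch": (synth.graded_pinch_population, synth.GRADED_PINCH),
    "feature_coding": (synth.feature_coding_population, synth.FEATURE_CODING),
}


@dataclass
class RunConfig:
    """All thresholds, window sizes, null sizes and seeds for one run."""

    outdir: str = "s1pop_out"
    seed: int = 0
    # input: either a simulated experiment or a recording/protocol pair
    experiment: str | None = "feature_coding"
    n_cells: int = 120
    noise_sigma: float = synth.NOISE_SIGMA
    trial_cv: float = synth.TRIAL_CV
    recording_path: str | None = None
    protocol_path: str | None = None
    # thresholds (fractions of F0 / of the mean PI)
    responder_threshold: float = 0.30
    tuned_factor: float = 0.8
    baseline_fraction: float = 0.30
    # windows
    post_window_s: float = 2.0
    pre_window_s: float = 2.0
    frame_period_s: float = synth.FRAME_PERIOD_S
    # geometry
    n_components: int = 3
    # permutation sizes
    n_reshuffles: int = 10_000
    n_permutations: int = 1000
    # decoding
    knn_k: int = 5
    n_folds: int = 10
    # stimulus pairs; None = all pairs differing in exactly one feature
    selectivity_pairs: list[tuple[str, str]] | None = None
    decode_pairs: list[tuple[str, str]] | None = None
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("responder_threshold", "tuned_factor", "baseline_fraction"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.post_window_s < 0 or self.pre_window_s < 0:
            raise ConfigError("window lengths must be >= 0")
        if self.n_reshuffles < 100:
            raise ConfigError("n_reshuffles must be >= 100")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.knn_k < 1 or self.n_folds < 2:
            raise ConfigError("knn_k must be >= 1 and n_folds >= 2")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        if self.experiment is None:
            if not (self.recording_path and self.protocol_path):
                raise ConfigError(
                    "either an experiment name or recording+protocol paths required"
                )
            for p in (self.recording_path, self.protocol_path):
                if not Path(p).exists():
                    raise ConfigError(f"input file not found: {p}")
        elif self.experiment not in EXPERIMENTS:
            raise ConfigError(
                f"unknown experiment {self.experiment!r}; "
                f"choose from {sorted(EXPERIMENTS)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("selectivity_pairs", "decode_pairs"):
            v = getattr(cfg, name)
            if v is not None:
                setattr(cfg, name, [tuple(p) for p in v])
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def single_feature_pairs(stimulus_info: pd.DataFrame) -> list[tuple[str, str]]:
    """All stimulus pairs differing in exactly one feature tag."""
    pairs = []
    for la, lb in combinations(stimulus_info.index, 2):
        a, b = stimulus_info.loc[la], stimulus_info.loc[lb]
        diffs = sum(
            a[f] != b[f] for f in ("texture", "dynamics", "noxiousness")
        )
        if diffs == 1:
            pairs.append((la, lb))
    return pairs


def run_pipeline(config: RunConfig) -> dict:
    """Execute preprocess -> tune -> geometry -> selectivity -> decode.

    Returns the summary dictionary that is also written to ``summary.json``.
    Any stage failure is re-raised with the stage name attached.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"config": dataclasses.asdict(config)}
    stage = "inputs"
    try:
        if config.experiment is not None:
            factory, spec = EXPERIMENTS[config.experiment]
            truth = factory(
                n_cells=config.n_cells,
                seed=config.seed,
                noise_sigma=config.noise_sigma,
                trial_cv=config.trial_cv,
            )
            protocol = synth.build_protocol(spec, seed=config.seed + 1)
            recording = synth.simulate_population(truth, protocol)
            pd.DataFrame(
                {"cell_id": recording.cell_ids, "cell_class": truth.cell_classes}
            ).to_csv(outdir / "truth.csv", index=False)
            sio.write_recording_csv(recording, outdir / "recording.csv")
            sio.write_protocol_csv(protocol, outdir / "protocol.csv")
            logger.info("simulated %s (%d cells, seed %d)",
                        config.experiment, config.n_cells, config.seed)
        else:
            recording = sio.read_recording_csv(config.recording_path)
            post = int(config.post_window_s / recording.frame_period_s)
            protocol = sio.read_protocol_csv(
                config.protocol_path, post_window_frames=post
            )
            sio.validate_pair(recording, protocol)

        stage = "preprocess"
        dff = compute_dff(recording, fraction=config.baseline_fraction)
        tensor = extract_trial_peaks(
            dff, protocol, response_threshold=config.responder_threshold
        )
        responders = detect_responders(tensor)
        resp_tensor = tensor.select_cells(responders)
        sio.write_tensor_json(resp_tensor, outdir / "tensor.json")
        summary["n_cells"] = tensor.n_cells
        summary["n_responders"] = int(responders.sum())
        logger.info("responders: %d / %d", responders.sum(), tensor.n_cells)

        stage = "tuning"
        profile = build_tuning_profile(resp_tensor, factor=config.tuned_factor)
        profile.to_dataframe().to_csv(outdir / "profile.csv")
        summary["broadly_tuned_fraction"] = float(profile.broadly_tuned.mean())
        info = resp_tensor.stimulus_info
        if len(resp_tensor.stimulus_labels) == 3:
            _, proportions = venn_categorize(
                profile.tuned, resp_tensor.stimulus_labels
            )
            summary["venn_proportions"] = proportions
        if info is not None and len(resp_tensor.stimulus_labels) == 4:
            try:
                classes = discriminative_class(
                    profile.tuned, resp_tensor.stimulus_labels, info
                )
                summary["discriminative_percent"] = {
                    c: float(100.0 * np.mean(classes == c))
                    for c in ("texture", "dynamics", "broad", "other", "none")
                }
            except PipelineError:
                pass  # not a 2x2 texture x dynamics design

        stage = "geometry"
        space = project_state_space(
            dff, protocol,
            n_components=config.n_components,
            pre_window_s=config.pre_window_s,
        )
        rows = []
        for la, lb in combinations(protocol.stimulus_labels, 2):
            mean, sem, n_pairs = interstate_distance(space, la, lb)
            rows.append(dict(condition_a=la, condition_b=lb,
                             mean=mean, sem=sem, n_pairs=n_pairs))
        distances = pd.DataFrame(rows)
        distances.to_csv(outdir / "state_distances.csv", index=False)
        summary["explained_variance_ratio"] = (
            space.explained_variance_ratio.tolist()
        )
        summary["state_distances"] = {
            f"{r['condition_a']}|{r['condition_b']}": r["mean"] for r in rows
        }
        dendro = cluster_stimuli(profile.pi, resp_tensor.stimulus_labels)
        summary["stimulus_merge_heights"] = dendro.merge_heights.tolist()

        stage = "selectivity"
        pairs = config.selectivity_pairs
        if pairs is None and info is not None:
            pairs = single_feature_pairs(info)
        summary["selectivity"] = []
        if pairs:
            non_broad = ~profile.broadly_tuned
            results = selectivity_tests(
                profile.pi[non_broad],
                resp_tensor.stimulus_labels,
                pairs,
                n_reshuffles=config.n_reshuffles,
                seed=config.seed + 100,
            )
            sel_df = pd.DataFrame(
                [
                    dict(
                        stimulus_a=r.feature_pair[0],
                        stimulus_b=r.feature_pair[1],
                        observed_mean_distance=r.observed_mean_distance,
                        null_mean=r.null_mean,
                        null_sd=r.null_sd,
                        z_distance=r.z_distance,
                        p_empirical=r.p_empirical,
                        p_adjusted=r.p_adjusted,
                        n_cells=r.n_cells,
                        n_reshuffles=r.n_reshuffles,
                        seed=r.seed,
                    )
                    for r in results
                ]
            )
            sel_df.to_csv(outdir / "selectivity.csv", index=False)
            summary["selectivity"] = sel_df.to_dict(orient="records")

        stage = "decoding"
        dec_pairs = config.decode_pairs
        if dec_pairs is None and info is not None:
            dec_pairs = single_feature_pairs(info)
        summary["decoding"] = []
        if dec_pairs:
            dec_rows = []
            for i, pair in enumerate(dec_pairs):
                tvs = build_trial_vectors([resp_tensor], pair)
                result = label_permutation_test(
                    tvs,
                    k=config.knn_k,
                    n_folds=min(config.n_folds, tvs.n_trials),
                    n_permutations=config.n_permutations,
                    seed=config.seed + 200 + i,
                )
                dec_rows.append(
                    dict(
                        stimulus_a=pair[0],
                        stimulus_b=pair[1],
                        mean_accuracy=result.mean_accuracy,
                        p_label_permutation=result.p_label_permutation,
                        k=result.k,
                        n_folds=result.n_folds,
                        n_permutations=result.n_permutations,
                        seed=result.seed,
                    )
                )
            dec_df = pd.DataFrame(dec_rows)
            dec_df.to_csv(outdir / "decoding.csv", index=False)
            summary["decoding"] = dec_rows
    except PipelineError as exc:
        logger.removeHandler(handler)
        handler.close()
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline complete; outputs in %s", outdir)
    logger.removeHandler(handler)
    handler.close()
    return summary
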