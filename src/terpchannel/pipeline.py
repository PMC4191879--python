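"""End-to-end pipeline: scores → channel prediction → endpoint → evaluation.

The run configuration is a flat key-value file with sections (read with the
stdlib config parser); every threshold has an embedded default so a minimal
config only names the input paths. Outputs are deterministic for a fixed
config and seed: a predictions CSV, an evaluation JSON (when truth labels
are provided), profile plots, and a log echoing the configuration and
package versions.
"""

from __future__ import annotations

import configparser
import json
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .channels import ChannelLibrary, default_library, read_channel_file
from .ranking import (
    DEFAULT_BINDER_THRESHOLD,
    DEFAULT_DESTABILIZATION_THRESHOLD,
    DEFAULT_TIE_THRESHOLD,
    evaluate_predictions,
    predict_endpoint,
    rank_channels,
)
from .scores import read_scores_csv

__all__ = ["RunConfig", "run_pipeline", "read_truth_tsv"]


class ValidationError(ValueError):
    """Bad configuration or invalid input (CLI exit code 2)."""


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips through the config file."""

    scores: str = ""
    library: str = ""  # empty → built-in default channel library
    truth: str = ""  # optional TSV: enzyme<TAB>channel<TAB>cluster
    out_dir: str = "terpchannel_out"
    tie_threshold: float = DEFAULT_TIE_THRESHOLD
    binder_threshold: float = DEFAULT_BINDER_THRESHOLD
    destabilization_threshold: float = DEFAULT_DESTABILIZATION_THRESHOLD
    evalue_threshold: float = 1e-10
    seed: int = 0
    sentinel_convention: str = "minus10"
    plot: bool = True

    def validate(self) -> None:
        if not self.scores:
            raise ValidationError("config: [paths] scores is required")
        if self.tie_threshold < 0:
            raise ValidationError("tie_threshold must be >= 0")
        if self.destabilization_threshold < 0:
            raise ValidationError("destabilization_threshold must be >= 0")
        if self.evalue_threshold <= 0:
            raise ValidationError("evalue_threshold must be > 0")
        if self.sentinel_convention not in ("plus100", "minus10"):
            raise ValidationError(
                f"unknown sentinel convention {self.sentinel_convention!r}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise ValidationError(f"config file {path} not found")
        cfg = cls()
        paths = parser["paths"] if parser.has_section("paths") else {}
        cfg.scores = paths.get("scores", cfg.scores)
        cfg.library = paths.get("library", cfg.library)
        cfg.truth = paths.get("truth", cfg.truth)
        cfg.out_dir = paths.get("out", cfg.out_dir)
        thr = parser["thresholds"] if parser.has_section("thresholds") else {}
        cfg.tie_threshold = float(thr.get("tie", cfg.tie_threshold))
        cfg.binder_threshold = float(thr.get("binder", cfg.binder_threshold))
        cfg.destabilization_threshold = float(
            thr.get("destabilization", cfg.destabilization_threshold)
        )
        cfg.evalue_threshold = float(thr.get("evalue", cfg.evalue_threshold))
        run = parser["run"] if parser.has_section("run") else {}
        cfg.seed = int(run.get("seed", cfg.seed))
        cfg.sentinel_convention = run.get("sentinel", cfg.sentinel_convention)
        cfg.plot = str(run.get("plot", cfg.plot)).lower() in ("true", "1", "yes")
        return cfg

    def to_text(self) -> str:
        return (
            "[paths]\n"
            f"scores = {self.scores}\n"
            f"library = {self.library}\n"
            f"truth = {self.truth}\n"
            f"out = {self.out_dir}\n\n"
            "[thresholds]\n"
            f"tie = {self.tie_threshold}\n"
            f"binder = {self.binder_threshold}\n"
            f"destabilization = {self.destabilization_threshold}\n"
            f"evalue = {self.evalue_threshold}\n\n"
            "[run]\n"
            f"seed = {self.seed}\n"
            f"sentinel = {self.sentinel_convention}\n"
            f"plot = {self.plot}\n"
        )


def read_truth_tsv(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Truth TSV (enzyme, channel, cluster) → (truth, clusters)."""
    truth: dict[str, str] = {}
    clusters: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"{path}:{lineno}: expected enzyme<TAB>channel<TAB>cluster"
            )
        truth[parts[0]] = parts[1]
        clusters[parts[0]] = parts[2]
    return truth, clusters


def _load_library(cfg: RunConfig) -> ChannelLibrary:
    return read_channel_file(cfg.library) if cfg.library else default_library()


def run_pipeline(config: RunConfig) -> dict:
    """Run scores → channel prediction → endpoint → evaluation.

    Writes ``predictions.csv``, ``evaluation.json`` (if truth given),
    profile plots and ``run.log`` into the output directory and returns the
    report as a dict. Reruns with the same config are byte-identical.
    """
    config.validate()
    lib = _load_library(config)
    table = read_scores_csv(config.scores, lib)
    if len(table) == 0:
        raise ValidationError(f"score table {config.scores} is empty")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pred_lines = ["enzyme,best_channel,ambiguous,ranked_channels,tie_group"]
    predictions: dict[str, str | None] = {}
    endpoints: dict[str, dict] = {}
    for enzyme in table.enzymes:
        cp = rank_channels(table, enzyme, lib, config.tie_threshold)
        predictions[enzyme] = cp.best_channel
        pred_lines.append(
            f"{enzyme},{cp.best_channel or ''},{int(cp.ambiguous)},"
            f"{'>'.join(cp.ranked_channels)},{';'.join(cp.tie_group)}"
        )
        if cp.best_channel is not None:
            chan = lib.channel(cp.best_channel)
            if all(table.get(enzyme, i.id) is not None for i in chan.intermediates):
                ep = predict_endpoint(
                    table, enzyme, cp.best_channel, lib, config.binder_threshold
                )
                endpoints[enzyme] = {
                    "channel": ep.channel,
                    "best_intermediate": ep.best_intermediate,
                    "terminate_after": ep.terminate_after,
                    "ruled_out_products": ep.ruled_out_products,
                    "rise_check_passed": ep.rise_check_passed,
                }
    (out / "predictions.csv").write_text("\n".join(pred_lines) + "\n")

    report: dict = {"n_enzymes": len(table.enzymes), "endpoints": endpoints}
    if config.truth:
        truth, clusters = read_truth_tsv(config.truth)
        report["evaluation"] = evaluate_predictions(predictions, truth, clusters)
    (out / "evaluation.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )

    if config.plot:
        from .plotting import plot_score_profiles

        channels_seen = sorted(
            {c for c in predictions.values() if c is not None}
        )
        for cid in channels_seen:
            enz = [e for e, c in predictions.items() if c == cid][:12]
            plot_score_profiles(
                table, enz, cid, lib, config.sentinel_convention,
                out=out / f"profiles_channel_{cid}.png",
            )

    log = [
        f"terpchannel {__version__}",
        "config:",
        config.to_text(),
        f"seed: {config.seed}",
        f"enzymes: {len(table.enzymes)}",
    ]
    (out / "run.log").write_text("\n".join(log) + "\n")
    return report


def config_defaults_text() -> str:
    """Default configuration, as printed by ``--show-config``."""
    return RunConfig().to_text()


def config_as_dict(config: RunConfig) -> dict:
    return asdict(config)
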