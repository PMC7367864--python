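"""End-to-end pipeline runner with a reproducibility manifest.

A :class:`PipelineConfig` fully captures one run (paths, seed, stage
options); deterministic stages reproduce their outputs bit-for-bit, which
the manifest records as content hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

from . import action_string
from .corpus import PairedSample, read_tsv, write_tsv
from .extractor import extract_sentence
from .fixtures import GeneratorConfig, generate_corpus, generate_pools
from .metrics import confusion_ledger, evaluate_predictions

logger = logging.getLogger("synthactions.pipeline")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """One reproducible run: workdir, seed, and per-stage options."""

    workdir: str
    seed: int = 0
    n_samples: int = 100
    noise: bool = False
    stages: tuple[str, ...] = ("fixtures", "extract", "evaluate")

    def to_dict(self) -> dict:
        return {
            "workdir": self.workdir,
            "seed": self.seed,
            "n_samples": self.n_samples,
            "noise": self.noise,
            "stages": list(self.stages),
        }


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns (and writes) the manifest.

    The manifest lists every produced file with its content hash, the seed
    used, and per-stage input/output counts.  Any stage error aborts with
    :class:`PipelineStageError` naming the stage.
    """
    os.makedirs(config.workdir, exist_ok=True)
    files: dict[str, str] = {}
    counts: dict[str, dict] = {}

    def path(name: str) -> str:
        return os.path.join(config.workdir, name)

    for stage in config.stages:
        logger.info("stage %s starting", stage)
        try:
            if stage == "fixtures":
                corpus = generate_corpus(
                    GeneratorConfig(
                        seed=config.seed, n_samples=config.n_samples, noise=config.noise
                    )
                )
                write_tsv(corpus, path("corpus.tsv"))
                generate_pools(config.seed).to_json(path("pools.json"))
                files["corpus.tsv"] = _sha256(path("corpus.tsv"))
                files["pools.json"] = _sha256(path("pools.json"))
                counts[stage] = {"in": 0, "out": len(corpus)}
            elif stage == "extract":
                samples = read_tsv(path("corpus.tsv"))
                predictions = [
                    action_string.serialize(extract_sentence(s.sentence))
                    for s in samples
                ]
                with open(path("predictions.txt"), "w", encoding="utf-8") as fh:
                    fh.write("\n".join(predictions) + "\n")
                with open(path("references.txt"), "w", encoding="utf-8") as fh:
                    fh.write("\n".join(s.action_string for s in samples) + "\n")
                files["predictions.txt"] = _sha256(path("predictions.txt"))
                files["references.txt"] = _sha256(path("references.txt"))
                counts[stage] = {"in": len(samples), "out": len(predictions)}
            elif stage == "evaluate":
                with open(path("predictions.txt"), encoding="utf-8") as fh:
                    predictions = [l.rstrip("\n") for l in fh if l.strip()]
                with open(path("references.txt"), encoding="utf-8") as fh:
                    references = [l.rstrip("\n") for l in fh if l.strip()]
                report = evaluate_predictions(predictions, references)
                ledger = confusion_ledger(
                    [action_string.parse(p) if action_string.try_parse(p).ok
                     else action_string.ActionSequence() for p in predictions],
                    [action_string.parse(r) for r in references],
                )
                with open(path("report.json"), "w", encoding="utf-8") as fh:
                    json.dump(
                        {"metrics": report.to_dict(), "confusion": ledger.to_dict()},
                        fh,
                        indent=1,
                    )
                files["report.json"] = _sha256(path("report.json"))
                counts[stage] = {"in": len(predictions), "out": 1}
            else:
                raise ValueError(f"unknown stage name: {stage}")
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc
        logger.info("stage %s done: %s", stage, counts.get(stage))

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "files": files,
        "counts": counts,
    }
    with open(path("manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
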