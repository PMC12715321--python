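"""Shared run configuration for the numbered analysis scripts.

All scripts operate on one run directory (default results/full_run) so each
stage can be rerun independently from the files the previous stage wrote.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from penstroke.classifier import ClassifierConfig
from penstroke.pipeline import RunConfig
from penstroke.synth import ArtifactParams, GeneratorConfig


def build_config(args: argparse.Namespace) -> RunConfig:
    generator = GeneratorConfig(
        dpi=args.dpi,
        artifact_params=None if args.clean else ArtifactParams(),
        seed=args.seed,
    )
    if args.small:
        n_per_group = {"HS": 6, "PD_OFF": 8}
        classifier = ClassifierConfig(epochs=5, folds=3, seed=args.seed + 2)
    else:
        # study-scale cohorts: 25 healthy subjects, 57 PD (stages alternate)
        n_per_group = {"HS": 25, "PD_OFF": 57}
        classifier = ClassifierConfig(epochs=8, folds=5, seed=args.seed + 2)
    return RunConfig(
        out_dir=args.run_dir,
        n_per_group=n_per_group,
        generator=generator,
        classifier=classifier,
        comparison="HS_vs_PD",
        seed_generation=args.seed,
        seed_training=args.seed + 2,
    )


def parser(description: str) -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--run-dir", type=Path, default=Path("results/full_run"))
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--dpi", type=float, default=300.0)
    p.add_argument("--clean", action="store_true",
                   help="render without smartphone-scan artifacts")
    p.add_argument("--small", action="store_true",
                   help="small demo cohort (6 HS + 8 PD) instead of 25 + 57")
    return p
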