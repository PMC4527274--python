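"""End-to-end orchestration: scan -> classify -> lipidation -> composition
(-> naming, -> evolution statistics) with a deterministic report bundle.

Each stage is also runnable standalone (see the CLI); the orchestrator
only sequences them and writes TSV/JSON outputs, so an orchestrated run
and the equivalent standalone runs produce identical numbers.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from ._version import __version__
from .composition_energy import CostTable, composition, cost_abundance_association
from .core_io import read_fasta
from .efhand_motifs import ScanRule, classify_cbl
from .evolution_stats import relative_rate_test, tajima_d_from_alignment, trio_counts
from .lipidation import call_lipidation, group_pattern_check

logger = logging.getLogger("cblkit.pipeline")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration for one orchestrated run."""

    fasta: Path
    out_dir: Path
    groups_tsv: Optional[Path] = None  # record_id<TAB>group for lipidation summary
    trio_fasta: Optional[Path] = None  # 3-sequence gapped FASTA for relative rate
    family_alignment: Optional[Path] = None  # gapped FASTA for neutrality test
    min_loop_matches: int = 3
    strict: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.fasta = Path(self.fasta)
        self.out_dir = Path(self.out_dir)
        if not self.fasta.exists():
            raise FileNotFoundError(f"input FASTA not found: {self.fasta}")
        for attr in ("groups_tsv", "trio_fasta", "family_alignment"):
            value = getattr(self, attr)
            if value is not None:
                value = Path(value)
                if not value.exists():
                    raise FileNotFoundError(f"{attr} not found: {value}")
                setattr(self, attr, value)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self) -> str:
        data = {k: (str(v) if isinstance(v, Path) else v)
                for k, v in self.__dict__.items() if v is not None}
        return yaml.safe_dump(data, sort_keys=True)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.3f s", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


@_stage("scan")
def _scan_stage(records, rule: ScanRule) -> pd.DataFrame:
    rows = []
    for rec in records:
        cls = classify_cbl(rec, rule)
        rows.append({
            "record_id": cls.record_id, "n_hands": cls.n_hands,
            "hand_starts": ",".join(str(s) for s in cls.hand_starts),
            "is_cbl": cls.is_cbl,
        })
    return pd.DataFrame(rows)


@_stage("lipidation")
def _lipidation_stage(records, groups: Optional[dict]) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    calls = [call_lipidation(rec) for rec in records]
    frame = pd.DataFrame([
        {
            "record_id": c.record_id, "myristoylation": c.myristoylation,
            "myristoylation_position": c.myristoylation_position,
            "palmitoylation_positions": ",".join(map(str, c.palmitoylation_positions)),
            "canonical_palmitoylation": c.canonical_palmitoylation,
            "group_b_like": c.group_b_like,
        }
        for c in calls
    ])
    summary = group_pattern_check(calls, groups) if groups else None
    return frame, summary


@_stage("composition")
def _composition_stage(records) -> tuple[pd.DataFrame, Optional[float]]:
    comp = composition(records)
    rho, table = cost_abundance_association(comp, CostTable())
    return table, rho


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and write the report bundle.

    Returns the JSON-serializable summary that is also written to
    ``summary.json`` in the output directory.
    """
    records = read_fasta(config.fasta)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    rule = ScanRule(min_loop_matches=config.min_loop_matches, strict=config.strict)

    summary: dict = {
        "version": __version__,
        "n_records": len(records),
        "seed": config.seed,
    }

    scan = _scan_stage(records, rule)
    scan.to_csv(config.out_dir / "scan.tsv", sep="\t", index=False)
    summary["n_cbl"] = int(scan["is_cbl"].sum())

    groups = None
    if config.groups_tsv is not None:
        gdf = pd.read_csv(config.groups_tsv, sep="\t", header=None,
                          names=["record_id", "group"])
        groups = dict(zip(gdf["record_id"], gdf["group"]))
    calls, group_summary = _lipidation_stage(records, groups)
    calls.to_csv(config.out_dir / "lipidation.tsv", sep="\t", index=False)
    if group_summary is not None:
        group_summary.to_csv(config.out_dir / "lipidation_groups.tsv",
                             sep="\t", index=False)
        summary["lipidation_groups"] = {
            row["group"]: row["frac_canonical_palmitoylation"]
            for _, row in group_summary.iterrows() if row["n"] > 0
        }

    comp_table, rho = _composition_stage(records)
    comp_table.to_csv(config.out_dir / "composition.tsv", sep="\t", index=False)
    summary["cost_abundance_spearman"] = rho

    if config.trio_fasta is not None:
        trio = read_fasta(config.trio_fasta, aligned=True)
        counts = trio_counts(trio)
        rr = relative_rate_test(counts)
        summary["relative_rate"] = {
            "unique_a": counts.unique_a, "unique_b": counts.unique_b,
            "chi2": round(rr.chi2, 2), "p": round(rr.p, 5),
        }

    if config.family_alignment is not None:
        block = read_fasta(config.family_alignment, aligned=True)
        res = tajima_d_from_alignment(block)
        summary["tajima_d"] = {
            "m": len(block),
            "theta_per_site": round(res.theta_per_site, 6),
            "D": round(res.D, 6),
        }

    with open(config.out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(config.out_dir / "config.yaml", "w") as fh:
        fh.write(config.to_yaml())
    return summary
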