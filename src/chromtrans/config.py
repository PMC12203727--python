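"""Run configuration: YAML + CSV manifests describing a full analysis."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .counting import DifferentiationOrder
from .intervals import GeneAnnotation, Segmentation, read_bed

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a run configuration is invalid or references missing files."""


@dataclass
class RunConfig:
    """Validated analysis configuration.

    ``samples`` rows carry (path, cell_type, replicate); paths are resolved
    relative to the config file location.
    """

    base_dir: Path
    samples: pd.DataFrame
    order: DifferentiationOrder
    bin_size: int
    state_labels: list[str]
    empty_state: str
    annotation_path: Path
    gene_set_paths: Mapping[str, Path] = field(default_factory=dict)
    seed: int = 0
    model: Mapping[str, object] = field(default_factory=dict)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent
        try:
            samples = pd.DataFrame(raw["samples"])
            order_types = list(raw["order"])
            bin_size = int(raw["bin_size"])
            state_labels = list(raw["state_labels"])
            empty_state = str(raw["empty_state"])
        except KeyError as exc:
            raise ConfigError(f"config missing required key: {exc}") from exc
        for col in ["path", "cell_type", "replicate"]:
            if col not in samples.columns:
                raise ConfigError(f"samples entries need a {col!r} field")
        samples["path"] = samples["path"].map(lambda p: base / p)
        for p in samples["path"]:
            if not Path(p).exists():
                raise ConfigError(f"sample file not found: {p}")
        sample_types = set(samples["cell_type"])
        if sample_types != set(order_types):
            raise ConfigError(
                f"order cell types {sorted(order_types)} do not match sample "
                f"cell types {sorted(sample_types)}"
            )
        if empty_state not in state_labels:
            raise ConfigError("empty_state must be listed in state_labels")
        reps = {
            ct: tuple(samples.loc[samples["cell_type"] == ct, "replicate"].astype(str))
            for ct in order_types
        }
        order = DifferentiationOrder(tuple(order_types), reps)

        annotation_path = base / raw.get("annotation", "genes.bed")
        if not annotation_path.exists():
            raise ConfigError(f"annotation file not found: {annotation_path}")
        gene_set_paths: dict[str, Path] = {}
        if "gene_sets" in raw and raw["gene_sets"]:
            manifest_path = base / raw["gene_sets"]
            if not manifest_path.exists():
                raise ConfigError(f"gene-set manifest not found: {manifest_path}")
            manifest = pd.read_csv(manifest_path)
            for col in ["gene_set", "path"]:
                if col not in manifest.columns:
                    raise ConfigError(f"gene-set manifest needs a {col!r} column")
            for r in manifest.itertuples():
                p = base / r.path
                if not p.exists():
                    raise ConfigError(f"gene-set file not found: {p}")
                gene_set_paths[str(r.gene_set)] = p
        return cls(
            base_dir=base,
            samples=samples,
            order=order,
            bin_size=bin_size,
            state_labels=state_labels,
            empty_state=empty_state,
            annotation_path=annotation_path,
            gene_set_paths=gene_set_paths,
            seed=int(raw.get("seed", 0)),
            model=dict(raw.get("model", {})),
        )

    def load_segmentations(self) -> list[Segmentation]:
        segs = []
        for r in self.samples.itertuples():
            seg = read_bed(
                r.path,
                dialect="segmentation",
                sample_id=f"{r.cell_type}_{r.replicate}",
                cell_type=str(r.cell_type),
                replicate=str(r.replicate),
            )
            seg.validate_states(self.state_labels)
            segs.append(seg)
        return segs

    def load_annotation(self) -> GeneAnnotation:
        return read_bed(self.annotation_path, dialect="annotation")

    def load_gene_sets(self) -> dict[str, list[str]]:
        sets = {}
        for set_id, p in self.gene_set_paths.items():
            sets[set_id] = [
                line.strip() for line in Path(p).read_text().splitlines() if line.strip()
            ]
        return sets
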