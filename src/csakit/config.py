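"""Plain-text (YAML) run configuration.

The config replaces a spreadsheet-style parameter workbook with a layered
document: a ``workflow`` name, an ``io`` section of paths, one optional
section per parameter group (``csa``, ``dda``, ``dia``, ``search``,
``aggregate``) and global ``threads``/``seed``.  Unknown keys anywhere
are rejected by name; every parameter is range-checked.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .ddia import DDAParams, DIAParams
from .deconv import CSAParams
from .errors import InputError, ValidationError
from .fsa import SearchParams

__all__ = ["RunConfig", "load_config"]

WORKFLOWS = (
    "csa", "dda", "dia", "aggregate", "build-db", "search", "summarize", "fixtures",
)

_TOP_KEYS = {"workflow", "io", "csa", "dda", "dia", "search", "aggregate",
             "threads", "seed"}
_IO_KEYS = {"scans", "peaklists", "aligned", "library", "queries", "fsdb",
            "output_dir", "targets"}
_AGG_KEYS = {"rt_window", "entsim_min", "fragment_mz_tol", "tanimoto_min", "quorum"}


@dataclass
class AggregateParams:
    rt_window: float = 0.1
    entsim_min: float = 0.75
    fragment_mz_tol: float = 0.01
    tanimoto_min: float = 0.5
    quorum: float = 0.5

    def validate(self) -> None:
        if self.rt_window <= 0:
            raise ValidationError(f"rt_window must be > 0: {self.rt_window}")
        if not (0.0 < self.entsim_min <= 1.0):
            raise ValidationError(f"entsim_min must be in (0, 1]: {self.entsim_min}")
        if not (0.0 <= self.tanimoto_min <= 1.0):
            raise ValidationError(f"tanimoto_min must be in [0, 1]: {self.tanimoto_min}")
        if not (0.0 < self.quorum <= 1.0):
            raise ValidationError(f"quorum must be in (0, 1]: {self.quorum}")

    @classmethod
    def from_dict(cls, d: dict) -> "AggregateParams":
        unknown = set(d) - _AGG_KEYS
        if unknown:
            raise ValidationError(f"unknown aggregate parameter(s): {sorted(unknown)}")
        params = cls(**d)
        params.validate()
        return params


@dataclass
class RunConfig:
    workflow: str = "csa"
    io: dict = field(default_factory=dict)
    csa: CSAParams = field(default_factory=CSAParams)
    dda: DDAParams = field(default_factory=DDAParams)
    dia: DIAParams = field(default_factory=DIAParams)
    search: SearchParams = field(default_factory=SearchParams)
    aggregate: AggregateParams = field(default_factory=AggregateParams)
    threads: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.workflow not in WORKFLOWS:
            raise ValidationError(
                f"workflow must be one of {WORKFLOWS}: {self.workflow}")
        if self.threads < 1:
            raise ValidationError(f"threads must be >= 1: {self.threads}")
        unknown = set(self.io) - _IO_KEYS
        if unknown:
            raise ValidationError(f"unknown io key(s): {sorted(unknown)}")
        for group in (self.csa, self.dda, self.dia, self.search, self.aggregate):
            group.validate()

    def manifest_hash(self) -> str:
        """Stable hash of the full parameter snapshot."""
        snapshot = {
            "workflow": self.workflow,
            "io": self.io,
            "csa": asdict(self.csa),
            "dda": asdict(self.dda),
            "dia": asdict(self.dia),
            "search": asdict(self.search),
            "aggregate": asdict(self.aggregate),
            "threads": self.threads,
            "seed": self.seed,
        }
        blob = json.dumps(snapshot, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def snapshot(self) -> dict:
        return {
            "workflow": self.workflow,
            "io": self.io,
            "csa": asdict(self.csa),
            "dda": asdict(self.dda),
            "dia": asdict(self.dia),
            "search": asdict(self.search),
            "aggregate": asdict(self.aggregate),
            "threads": self.threads,
            "seed": self.seed,
            "hash": self.manifest_hash(),
        }


def load_config(path: str) -> RunConfig:
    """Parse and validate a YAML run configuration, filling defaults."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise InputError(f"config file not found: {path}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValidationError(f"config root must be a mapping: {path}")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    config = RunConfig(
        workflow=str(doc.get("workflow", "csa")),
        io=dict(doc.get("io", {}) or {}),
        csa=CSAParams.from_dict(doc.get("csa", {}) or {}),
        dda=DDAParams.from_dict(doc.get("dda", {}) or {}),
        dia=DIAParams.from_dict(doc.get("dia", {}) or {}),
        search=SearchParams.from_dict(doc.get("search", {}) or {}),
        aggregate=AggregateParams.from_dict(doc.get("aggregate", {}) or {}),
        threads=int(doc.get("threads", 1)),
        seed=int(doc.get("seed", 0)),
    )
    config.validate()
    return config
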