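"""Run configuration, CSV interchange and run-manifest capture.

Configuration is a flat YAML file holding run parameters plus either an
explicit ``scenarios`` list or a ``grid`` block whose Cartesian product is
expanded (the study's grid is 3 sizes x 2 treatment prevalences x 2 outcome
prevalences x 3 true ORs = 36 scenarios).  All interchange is header-row CSV;
floats are serialised with ``repr`` so a write/read round trip is bit-exact.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from itertools import product
from pathlib import Path
from typing import Sequence

import yaml

from .dgp import Scenario
from .engine import QUANTILE_CONVENTION, ReplicationSummary

__all__ = [
    "RunConfig",
    "RunManifest",
    "load_config",
    "paper_grid",
    "write_summary",
    "read_summary",
]

_ALGORITHMS = ("caliper_random", "nn_caliper")

_RUN_KEYS = {"reps", "base_seed", "algorithms", "caliper_multipliers",
             "scenarios", "grid"}
_SCENARIO_KEYS = {"n", "p_treat", "p_outcome", "true_or", "seed"}
_GRID_KEYS = {"n", "p_treat", "p_outcome", "true_or"}


@dataclass
class RunConfig:
    """Validated scenario grid plus run parameters."""

    scenarios: list[Scenario]
    reps: int = 1000
    base_seed: int = 0
    algorithms: tuple[str, ...] = _ALGORITHMS
    caliper_multipliers: tuple[float, ...] = (0.2, 0.01)


def default_grid(
    *,
    n: Sequence[int] = (500, 2500, 10000),
    p_treat: Sequence[float] = (0.2, 0.5),
    p_outcome: Sequence[float] = (0.1, 0.5),
    true_or: Sequence[float] = (0.75, 1.0, 1.5),
    base_seed: int = 0,
) -> list[Scenario]:
    """Cartesian scenario grid; each cell gets its own derived cohort seed."""
    scenarios = []
    for i, (nn, pt, po, tor) in enumerate(product(n, p_treat, p_outcome, true_or)):
        scenarios.append(Scenario(
            n=int(nn), p_treat=float(pt), p_outcome=float(po), true_or=float(tor),
            seed=(int(base_seed) + 104_729 * (i + 1)) % 2**31,
        ))
    return scenarios


def paper_grid(base_seed: int = 0) -> list[Scenario]:
    """The study's full 36-scenario grid."""
    return default_grid(base_seed=base_seed)


def _fail(path: str, msg: str) -> "ValueError":
    return ValueError(f"config {path}: {msg}")


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Unknown keys are rejected (with their key path) rather than ignored, so
    typos cannot silently change a run.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise _fail("<root>", "expected a mapping")
    unknown = set(raw) - _RUN_KEYS
    if unknown:
        raise _fail(sorted(unknown)[0], "unknown key")

    reps = int(raw.get("reps", 1000))
    if reps < 1:
        raise _fail("reps", "must be >= 1")
    base_seed = int(raw.get("base_seed", 0))
    algorithms = tuple(raw.get("algorithms", list(_ALGORITHMS)))
    for a in algorithms:
        if a not in _ALGORITHMS:
            raise _fail(f"algorithms.{a}", "unknown algorithm")
    multipliers = tuple(float(m) for m in raw.get("caliper_multipliers", [0.2, 0.01]))
    if any(m <= 0 for m in multipliers):
        raise _fail("caliper_multipliers", "must be positive")

    if ("scenarios" in raw) == ("grid" in raw):
        raise _fail("<root>", "exactly one of 'scenarios' or 'grid' is required")

    scenarios: list[Scenario] = []
    if "grid" in raw:
        grid = raw["grid"]
        if not isinstance(grid, dict):
            raise _fail("grid", "expected a mapping")
        unknown = set(grid) - _GRID_KEYS
        if unknown:
            raise _fail(f"grid.{sorted(unknown)[0]}", "unknown key")
        try:
            scenarios = default_grid(
                n=grid.get("n", (500, 2500, 10000)),
                p_treat=grid.get("p_treat", (0.2, 0.5)),
                p_outcome=grid.get("p_outcome", (0.1, 0.5)),
                true_or=grid.get("true_or", (0.75, 1.0, 1.5)),
                base_seed=base_seed,
            )
        except ValueError as exc:
            raise _fail("grid", str(exc)) from exc
    else:
        entries = raw["scenarios"]
        if not isinstance(entries, list) or not entries:
            raise _fail("scenarios", "expected a non-empty list")
        for i, entry in enumerate(entries):
            if not isinstance(entry, dict):
                raise _fail(f"scenarios[{i}]", "expected a mapping")
            unknown = set(entry) - _SCENARIO_KEYS
            if unknown:
                raise _fail(f"scenarios[{i}].{sorted(unknown)[0]}", "unknown key")
            try:
                scenarios.append(Scenario(
                    n=int(entry.get("n", 10000)),
                    p_treat=float(entry.get("p_treat", 0.5)),
                    p_outcome=float(entry.get("p_outcome", 0.5)),
                    true_or=float(entry.get("true_or", 1.0)),
                    seed=int(entry.get("seed", base_seed)),
                ))
            except ValueError as exc:
                raise _fail(f"scenarios[{i}]", str(exc)) from exc

    return RunConfig(
        scenarios=scenarios, reps=reps, base_seed=base_seed,
        algorithms=algorithms, caliper_multipliers=multipliers,
    )


# ---------------------------------------------------------------------------
# Summary CSV round trip
# ---------------------------------------------------------------------------

_SUMMARY_SCHEMA: dict[str, type] = {
    "scenario": str, "algorithm": str, "caliper_multiplier": float,
    "reps": int, "median_or": float, "iqr_low": float, "iqr_high": float,
    "range_low": float, "range_high": float, "crude_or": float,
    "pct_sig_low": float, "pct_sig_high": float,
    "mean_matched_subjects": float, "pct_unsuccessful": float,
    "n_undefined": int, "valid": bool,
}


def _encode(value, typ) -> str:
    if typ is bool:
        return "true" if value else "false"
    if typ is float:
        return repr(float(value))  # shortest exact decimal: bit-exact round trip
    return str(value)


def _decode(text: str, typ):
    if typ is bool:
        return text == "true"
    if typ is float:
        return float(text)
    if typ is int:
        return int(text)
    return text


def write_summary(path, rows: Sequence[ReplicationSummary]) -> None:
    """Write summary rows as CSV; an empty list yields a header-only file."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SUMMARY_SCHEMA)
        for row in rows:
            writer.writerow(
                _encode(getattr(row, name), typ)
                for name, typ in _SUMMARY_SCHEMA.items()
            )


def read_summary(path) -> list[ReplicationSummary]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != list(_SUMMARY_SCHEMA):
            raise ValueError(f"malformed summary file {path}: unexpected header")
        rows = []
        for record in reader:
            if len(record) != len(header):
                raise ValueError(f"malformed summary row in {path}: {record!r}")
            kwargs = {
                name: _decode(text, typ)
                for (name, typ), text in zip(_SUMMARY_SCHEMA.items(), record)
            }
            rows.append(ReplicationSummary(**kwargs))
        return rows


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance of one run: seeds, grid digest and conventions.

    The digest covers everything that determines the output bytes, so two
    runs with equal manifests (timestamps aside) produce identical CSVs.
    """

    master_seed: int
    reps: int
    algorithms: tuple[str, ...]
    caliper_multipliers: tuple[float, ...]
    grid_digest: str
    quantile_convention: str = QUANTILE_CONVENTION
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @classmethod
    def for_run(cls, config: RunConfig) -> "RunManifest":
        digest = hashlib.sha256(json.dumps([
            (s.n, s.p_treat, s.p_outcome, s.true_or, s.seed)
            for s in config.scenarios
        ]).encode()).hexdigest()[:16]
        return cls(
            master_seed=config.base_seed,
            reps=config.reps,
            algorithms=tuple(config.algorithms),
            caliper_multipliers=tuple(config.caliper_multipliers),
            grid_digest=digest,
        )

    def write(self, path) -> None:
        data = {**self.__dict__,
                "algorithms": list(self.algorithms),
                "caliper_multipliers": list(self.caliper_multipliers)}
        Path(path).write_text(json.dumps(data, indent=2) + "\n")


def nan_equal(a: float, b: float) -> bool:
    """Equality that treats NaN as equal to NaN (round-trip checks)."""
    return (a == b) or (math.isnan(a) and math.isnan(b))
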