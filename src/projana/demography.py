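"""Backward-time demographic models for serial-sampling coalescent simulation.

A :class:`DemographicModel` describes one or more panmictic demes with
piecewise-constant diploid effective sizes, population splits (backward-time
merges of a derived deme into its ancestor), instantaneous pulse admixture,
and sampling groups that may enter the genealogy at different past times
("serial sampling").  Times are measured in generations before the present
(0 = today) and sizes are diploid effective population sizes.

Any numeric field may instead hold the *name* of a free parameter declared in
``named_parameters``; :meth:`DemographicModel.bind` substitutes concrete
values.  This is how demographic fitting explores parameter space without
rebuilding model structure.

Models round-trip losslessly through plain dictionaries and YAML, so a
demography can live in a configuration file next to the data it describes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, Union

import yaml

__all__ = [
    "Deme",
    "PopulationSplit",
    "PulseAdmixture",
    "SampleGroup",
    "DemographicModel",
    "ModelValidationError",
]

#: A model field that is either a concrete number or the name of a free
#: parameter to be resolved by :meth:`DemographicModel.bind`.
Param = Union[float, int, str]


class ModelValidationError(ValueError):
    """Raised when a demographic model is structurally inconsistent."""


def _resolve(value: Param, params: Mapping[str, float], what: str) -> float:
    if isinstance(value, str):
        if value not in params:
            raise ModelValidationError(
                f"{what} references unknown named parameter {value!r}"
            )
        return float(params[value])
    return float(value)


@dataclass(frozen=True)
class Deme:
    """A panmictic population with a piecewise-constant size history.

    ``size_epochs`` is an ordered sequence of ``(start_time, diploid_size)``
    pairs; each size applies from its start time (generations ago) backward
    until the next epoch begins.  The first epoch must start at time 0.
    """

    name: str
    size_epochs: tuple = ((0.0, 1000.0),)

    def __post_init__(self):
        object.__setattr__(
            self, "size_epochs", tuple((t, n) for t, n in self.size_epochs)
        )


@dataclass(frozen=True)
class PopulationSplit:
    """Divergence of ``derived`` from ``ancestral`` at ``time`` generations ago.

    Backward in time, every lineage in the derived deme moves into the
    ancestral deme at the split time and the derived deme ceases to exist
    further in the past.
    """

    time: Param
    derived: str
    ancestral: str


@dataclass(frozen=True)
class PulseAdmixture:
    """Instantaneous admixture: ``source`` contributes fraction ``fraction``
    of the ancestry of ``recipient`` at ``time`` generations ago.

    Backward in time, each lineage in the recipient independently moves to
    the source deme with probability ``fraction``.
    """

    time: Param
    source: str
    recipient: str
    fraction: Param


@dataclass(frozen=True)
class SampleGroup:
    """Lineages entering the genealogy from ``deme`` at ``time`` generations ago.

    ``role`` is ``"panel"`` for reference-panel chromosomes or ``"test"`` for
    the single test lineage (the pseudo-haploid test genome).
    """

    deme: str
    time: Param
    lineages: int
    role: str = "panel"


_EVENT_KINDS = {"split": PopulationSplit, "pulse_admixture": PulseAdmixture}


@dataclass(frozen=True)
class DemographicModel:
    demes: tuple
    events: tuple = ()
    samples: tuple = ()
    named_parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "demes", tuple(self.demes))
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "named_parameters", dict(self.named_parameters))

    # ------------------------------------------------------------------
    # parameter binding
    # ------------------------------------------------------------------
    def bind(self, overrides: Mapping[str, float] | None = None) -> "DemographicModel":
        """Return a copy with every named-parameter reference replaced by its
        concrete value.  ``overrides`` updates ``named_parameters`` first."""
        params = dict(self.named_parameters)
        if overrides:
            unknown = set(overrides) - set(params)
            if unknown and self.named_parameters:
                # allow introducing brand-new names only on parameter-free models
                pass
            params.update(overrides)

        demes = tuple(
            Deme(
                d.name,
                tuple(
                    (
                        _resolve(t, params, f"deme {d.name} epoch start"),
                        _resolve(n, params, f"deme {d.name} epoch size"),
                    )
                    for t, n in d.size_epochs
                ),
            )
            for d in self.demes
        )
        events = []
        for ev in self.events:
            if isinstance(ev, PopulationSplit):
                events.append(
                    PopulationSplit(
                        _resolve(ev.time, params, "split time"), ev.derived, ev.ancestral
                    )
                )
            else:
                events.append(
                    PulseAdmixture(
                        _resolve(ev.time, params, "pulse time"),
                        ev.source,
                        ev.recipient,
                        _resolve(ev.fraction, params, "pulse fraction"),
                    )
                )
        samples = tuple(
            SampleGroup(
                s.deme,
                _resolve(s.time, params, "sample time"),
                int(s.lineages),
                s.role,
            )
            for s in self.samples
        )
        bound = DemographicModel(demes, tuple(events), samples, params)
        bound.validate()
        return bound

    @property
    def is_bound(self) -> bool:
        for d in self.demes:
            if any(isinstance(v, str) for tn in d.size_epochs for v in tn):
                return False
        for ev in self.events:
            vals = (
                (ev.time, ev.fraction)
                if isinstance(ev, PulseAdmixture)
                else (ev.time,)
            )
            if any(isinstance(v, str) for v in vals):
                return False
        return not any(isinstance(s.time, str) for s in self.samples)

    # ------------------------------------------------------------------
    # structure queries
    # ------------------------------------------------------------------
    def deme_index(self, name: str) -> int:
        for i, d in enumerate(self.demes):
            if d.name == name:
                return i
        raise KeyError(name)

    @property
    def panel_size(self) -> int:
        return sum(s.lineages for s in self.samples if s.role == "panel")

    @property
    def test_group(self) -> SampleGroup | None:
        for s in self.samples:
            if s.role == "test":
                return s
        return None

    def split_time(self, deme: str) -> float | None:
        """Time at which ``deme`` merges into its ancestor, or None for the root."""
        for ev in self.events:
            if isinstance(ev, PopulationSplit) and ev.derived == deme:
                return ev.time
        return None

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check structural consistency; only callable on a bound model."""
        if not self.is_bound:
            raise ModelValidationError("model has unresolved named parameters; bind() first")
        names = [d.name for d in self.demes]
        if len(set(names)) != len(names):
            raise ModelValidationError("duplicate deme names")
        name_set = set(names)

        for d in self.demes:
            if not d.size_epochs:
                raise ModelValidationError(f"deme {d.name} has no size epochs")
            starts = [t for t, _ in d.size_epochs]
            if starts[0] != 0:
                raise ModelValidationError(f"deme {d.name}: first epoch must start at 0")
            if any(b <= a for a, b in zip(starts, starts[1:])):
                raise ModelValidationError(f"deme {d.name}: epoch starts must increase")
            if any(n <= 0 for _, n in d.size_epochs):
                raise ModelValidationError(f"deme {d.name}: sizes must be positive")

        split_sources = {}
        for ev in self.events:
            if ev.time < 0:
                raise ModelValidationError("event times must be non-negative")
            if isinstance(ev, PopulationSplit):
                if ev.derived not in name_set or ev.ancestral not in name_set:
                    raise ModelValidationError(f"split references unknown deme: {ev}")
                if ev.derived == ev.ancestral:
                    raise ModelValidationError("split derived == ancestral")
                if ev.derived in split_sources:
                    raise ModelValidationError(
                        f"deme {ev.derived} is the derived deme of two splits"
                    )
                split_sources[ev.derived] = ev
            else:
                if ev.source not in name_set or ev.recipient not in name_set:
                    raise ModelValidationError(f"pulse references unknown deme: {ev}")
                if not (0.0 <= ev.fraction <= 1.0):
                    raise ModelValidationError("pulse fraction must be in [0, 1]")

        roots = name_set - set(split_sources)
        if len(roots) != 1:
            raise ModelValidationError(
                f"model must have exactly one root deme; demes never merged: {sorted(roots)}"
            )

        # split chain must reach the root with non-decreasing merge times
        def merge_time(deme: str) -> float:
            return split_sources[deme].time if deme in split_sources else float("inf")

        for deme, ev in split_sources.items():
            if merge_time(ev.ancestral) <= ev.time and ev.ancestral in split_sources:
                raise ModelValidationError(
                    f"deme {deme} merges into {ev.ancestral} at {ev.time} but "
                    f"{ev.ancestral} was already merged away"
                )

        for ev in self.events:
            if isinstance(ev, PulseAdmixture):
                for deme in (ev.source, ev.recipient):
                    if merge_time(deme) < ev.time:
                        raise ModelValidationError(
                            f"pulse at {ev.time} references deme {deme} merged earlier"
                        )

        test_groups = [s for s in self.samples if s.role == "test"]
        if len(test_groups) > 1:
            raise ModelValidationError("at most one test sample group allowed")
        if test_groups and test_groups[0].lineages != 1:
            raise ModelValidationError("the test sample group must hold exactly 1 lineage")
        for s in self.samples:
            if s.deme not in name_set:
                raise ModelValidationError(f"sample references unknown deme {s.deme}")
            if s.lineages < 1:
                raise ModelValidationError("sample groups need at least one lineage")
            if s.time < 0:
                raise ModelValidationError("sampling times must be non-negative")
            if merge_time(s.deme) < s.time:
                raise ModelValidationError(
                    f"sample at {s.time} in deme {s.deme}, which merged away earlier "
                    "(lineages would be stranded)"
                )
            if s.role not in ("panel", "test"):
                raise ModelValidationError(f"unknown sample role {s.role!r}")

    # ------------------------------------------------------------------
    # (de)serialisation
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        events = []
        for ev in self.events:
            if isinstance(ev, PopulationSplit):
                events.append(
                    {"kind": "split", "time": ev.time, "derived": ev.derived,
                     "ancestral": ev.ancestral}
                )
            else:
                events.append(
                    {"kind": "pulse_admixture", "time": ev.time, "source": ev.source,
                     "recipient": ev.recipient, "fraction": ev.fraction}
                )
        return {
            "demes": [
                {"name": d.name, "size_epochs": [list(e) for e in d.size_epochs]}
                for d in self.demes
            ],
            "events": events,
            "samples": [
                {"deme": s.deme, "time": s.time, "lineages": s.lineages, "role": s.role}
                for s in self.samples
            ],
            "named_parameters": dict(self.named_parameters),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "DemographicModel":
        demes = tuple(
            Deme(d["name"], tuple(tuple(e) for e in d["size_epochs"]))
            for d in data["demes"]
        )
        events = []
        for ev in data.get("events", []):
            kind = ev["kind"]
            if kind == "split":
                events.append(PopulationSplit(ev["time"], ev["derived"], ev["ancestral"]))
            elif kind == "pulse_admixture":
                events.append(
                    PulseAdmixture(ev["time"], ev["source"], ev["recipient"], ev["fraction"])
                )
            else:
                raise ModelValidationError(f"unknown event kind {kind!r}")
        samples = tuple(
            SampleGroup(s["deme"], s["time"], int(s["lineages"]), s.get("role", "panel"))
            for s in data.get("samples", [])
        )
        return cls(demes, tuple(events), samples, dict(data.get("named_parameters", {})))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "DemographicModel":
        """Load from a YAML string or a file path."""
        text = source
        try:
            import os

            if os.path.exists(str(source)):
                with open(source) as fh:
                    text = fh.read()
        except (OSError, ValueError):
            pass
        return cls.from_dict(yaml.safe_load(text))
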