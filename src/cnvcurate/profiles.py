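"""Caller profiles: where each quality metric lives in a caller's VCF.

Caller output dialects differ — the same conceptual metric (a p-value, a
Bayes factor, a copy-number quality score) may sit in INFO or in the
per-sample FORMAT fields under a caller-chosen key. A :class:`CallerProfile`
declares, per caller, the mapping from the metric names the confidence
filters use to ``INFO/<key>`` or ``FORMAT/<key>`` locations, so the filters
themselves never touch VCF machinery.

Profiles are plain YAML::

    caller: cnvpytor
    metrics:
      pytorP1: INFO/pytorP1
      Q0: INFO/Q0
      pytorRD: INFO/pytorRD
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

# filters and their required metrics are registered in caller_filters; the
# default profiles below assume the metric key equals the metric name in INFO,
# which is also the dialect cnvcurate's own VCF writer emits.
_DEFAULT_METRICS = {
    "cnvpytor": ["pytorP1", "Q0", "pytorRD"],
    "controlfreec": ["W", "KS"],
    "delly": [],
    "manta": [],
    "lumpy": [],
    "wham": ["max_CW", "TF", "U"],
    "gridss": [],
    "exomedepth": ["BF", "reads_ratio"],
    "gatk4": ["QS", "CN", "nt"],
    "cn.mops": [],
    "xhmm": [],
    "ecole": [],
    "cutesv": [],
    "svision-pro": [],
    "sniffles": [],
    "nanovar": [],
    "debreak": [],
}

KNOWN_CALLERS = tuple(_DEFAULT_METRICS)


@dataclass
class CallerProfile:
    """Mapping from metric names to VCF INFO/FORMAT locations for one caller."""

    caller: str
    metrics: dict = field(default_factory=dict)  # name -> ("INFO"|"FORMAT", key)

    @classmethod
    def default(cls, caller: str) -> "CallerProfile":
        caller = caller.lower()
        if caller not in _DEFAULT_METRICS:
            raise KeyError(
                f"unknown caller {caller!r}; known callers: {', '.join(KNOWN_CALLERS)}")
        return cls(caller=caller,
                   metrics={m: ("INFO", m) for m in _DEFAULT_METRICS[caller]})

    @classmethod
    def from_yaml(cls, path) -> "CallerProfile":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        metrics = {}
        for name, loc in (doc.get("metrics") or {}).items():
            where, _, key = str(loc).partition("/")
            if where not in ("INFO", "FORMAT") or not key:
                raise ValueError(
                    f"metric {name!r}: location must be INFO/<key> or FORMAT/<key>, "
                    f"got {loc!r}")
            metrics[name] = (where, key)
        return cls(caller=str(doc["caller"]).lower(), metrics=metrics)

    @classmethod
    def identity(cls, caller: str, metric_names) -> "CallerProfile":
        """Profile reading every metric from an identically-named INFO key."""
        return cls(caller=caller, metrics={m: ("INFO", m) for m in metric_names})
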