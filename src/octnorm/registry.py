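"""Registry of the 24 OCT thickness metrics and their covariate rules.

Seventeen metrics belong to the circumpapillary RNFL family (global average,
4 quadrants, 12 clock hours) and are modelled with age and disc area as
covariates.  Seven belong to the macular GCL+ family (global average within
the central +/-10 degrees and its 6 sectors) and use age only.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class MetricSpec:
    """One thickness metric and the covariates its normative model uses."""

    name: str
    family: str  # "cpRNFL" | "GCLplus"
    covariates: tuple[str, ...] = field(default=("age",))

    def __post_init__(self) -> None:
        if self.family not in ("cpRNFL", "GCLplus"):
            raise ValueError(f"unknown metric family {self.family!r}")
        for c in self.covariates:
            if c not in ("age", "disc_area"):
                raise ValueError(f"unknown covariate {c!r}")

    @property
    def n_coefficients(self) -> int:
        return 1 + len(self.covariates)


def _build_registry() -> dict[str, MetricSpec]:
    reg: dict[str, MetricSpec] = {}
    cp_cov = ("age", "disc_area")
    reg["g_cpRNFL"] = MetricSpec("g_cpRNFL", "cpRNFL", cp_cov)
    for q in "TSNI":
        name = f"cpRNFL_quadrant_{q}"
        reg[name] = MetricSpec(name, "cpRNFL", cp_cov)
    for h in range(1, 13):
        name = f"cpRNFL_clock_{h}"
        reg[name] = MetricSpec(name, "cpRNFL", cp_cov)
    reg["g_GCLplus"] = MetricSpec("g_GCLplus", "GCLplus", ("age",))
    for s in range(1, 7):
        name = f"GCLplus_sector_{s}"
        reg[name] = MetricSpec(name, "GCLplus", ("age",))
    return reg


#: All 24 registered metrics, in report order.
METRICS: dict[str, MetricSpec] = _build_registry()

#: The 2 global metrics the headline analysis focuses on.
GLOBAL_METRICS: tuple[str, str] = ("g_cpRNFL", "g_GCLplus")

#: The 22 local metrics (quadrants, clock hours, GCL+ sectors).
LOCAL_METRICS: tuple[str, ...] = tuple(
    m for m in METRICS if m not in GLOBAL_METRICS
)

CPRNFL_METRICS: tuple[str, ...] = tuple(
    m for m, s in METRICS.items() if s.family == "cpRNFL"
)
GCLPLUS_METRICS: tuple[str, ...] = tuple(
    m for m, s in METRICS.items() if s.family == "GCLplus"
)

assert len(CPRNFL_METRICS) == 17 and len(GCLPLUS_METRICS) == 7


def get_metric(name: str) -> MetricSpec:
    """Look up a metric by name, raising ``KeyError`` with the known names."""
    try:
        return METRICS[name]
    except KeyError:
        raise KeyError(
            f"unknown metric {name!r}; registered metrics: {', '.join(METRICS)}"
        ) from None
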