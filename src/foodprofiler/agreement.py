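"""Inter-system agreement analysis on the healthy/unhealthy dichotomy.

Each system's outcome collapses to healthy (Group A / marketing permitted /
logo-eligible / non-UPF) or unhealthy; products any system cannot classify
are dropped, so statistics run on the complete-case sample.  Pairwise
agreement is Cohen's kappa on the 2x2 cross-tabulation:

    po = (n11 + n22) / n
    pe = [(n11+n12)(n11+n21) + (n21+n22)(n12+n22)] / n^2
    kappa = (po - pe) / (1 - pe)

with the conventional interpretation bands (none-to-slight 0.01-0.20, fair
0.21-0.40, moderate 0.41-0.60, substantial 0.61-0.80, almost perfect
0.81-1.00; banding is applied to the kappa rounded to 2 decimals, and
reported kappas are rounded half-up to 3 decimals).
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .nova import NovaClass
from .profiling import ClassificationResult, DOHLabel, HCLLabel, System, WHOSEALabel

__all__ = [
    "SYSTEMS",
    "HealthFlag",
    "HealthFlags",
    "CrossTab2x2",
    "KappaResult",
    "KappaBand",
    "SystemsMetDistribution",
    "dichotomize",
    "restrict_to_complete",
    "crosstab_2x2",
    "cohen_kappa",
    "interpret_kappa",
    "systems_met_distribution",
    "upf_share_among_healthy",
    "build_report",
    "report_from_crosstabs",
    "reference_counts",
    "reference_crosstabs",
    "round_half_up",
]

SYSTEMS: tuple[str, ...] = ("DOH", "WHO_SEA", "HCL", "NOVA")


class HealthFlag(str, Enum):
    HEALTHY = "HEALTHY"
    UNHEALTHY = "UNHEALTHY"
    NOT_CLASSIFIABLE = "NOT_CLASSIFIABLE"


class HealthFlags(BaseModel):
    model_config = ConfigDict(frozen=True)

    product_id: str
    flags: dict[str, HealthFlag]

    @model_validator(mode="after")
    def _all_systems(self) -> "HealthFlags":
        if set(self.flags) != set(SYSTEMS):
            raise ValueError(f"flags must cover exactly {SYSTEMS}")
        return self

    @property
    def complete(self) -> bool:
        return all(f is not HealthFlag.NOT_CLASSIFIABLE for f in self.flags.values())

    @property
    def n_healthy(self) -> int:
        return sum(f is HealthFlag.HEALTHY for f in self.flags.values())


class CrossTab2x2(BaseModel):
    """Dichotomized agreement counts; n11 = both unhealthy, n22 = both healthy."""

    model_config = ConfigDict(frozen=True)

    labels: tuple[str, str]
    n11: int = Field(ge=0)
    n12: int = Field(ge=0)
    n21: int = Field(ge=0)
    n22: int = Field(ge=0)

    @property
    def n(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22


class KappaBand(str, Enum):
    NEGATIVE = "negative"
    ZERO = "zero"
    NONE_TO_SLIGHT = "none_to_slight"
    FAIR = "fair"
    MODERATE = "moderate"
    SUBSTANTIAL = "substantial"
    ALMOST_PERFECT = "almost_perfect"


class KappaResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    po: float = Field(ge=0, le=1)
    pe: float = Field(ge=0, le=1)
    kappa: float = Field(ge=-1, le=1)
    percent_agreement: float
    band: KappaBand
    degenerate: bool = False

    @property
    def kappa_3dp(self) -> float:
        return round_half_up(self.kappa, 3)


class SystemsMetDistribution(BaseModel):
    """Counts of products meeting the healthy criteria of exactly k systems."""

    model_config = ConfigDict(frozen=True)

    counts: tuple[int, int, int, int, int]

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def percentages(self) -> tuple[float, ...]:
        return tuple(100.0 * c / self.n for c in self.counts)


def round_half_up(x: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


_HEALTHY_DOH = {DOHLabel.GROUP_A.value}
_UNHEALTHY_DOH = {
    DOHLabel.GROUP_B.value,
    DOHLabel.GROUP_C.value,
    DOHLabel.AUTO_PROHIBITED.value,
}


def dichotomize(
    product_id: str,
    doh: ClassificationResult,
    whosea: ClassificationResult,
    hcl: ClassificationResult,
    nova: NovaClass,
) -> HealthFlags:
    """Collapse per-system outcomes to the healthy/unhealthy dichotomy.

    DOH healthy is Group A only (the marketing layer is reported
    separately); NOVA healthy is non-UPF (MP, PCI or P combined).
    Not-classifiable outcomes propagate.
    """

    def _profile_flag(result: ClassificationResult, healthy: set, unhealthy: set) -> HealthFlag:
        if result.label in healthy:
            return HealthFlag.HEALTHY
        if result.label in unhealthy:
            return HealthFlag.UNHEALTHY
        return HealthFlag.NOT_CLASSIFIABLE

    if nova is NovaClass.NOT_CLASSIFIABLE:
        nova_flag = HealthFlag.NOT_CLASSIFIABLE
    elif nova is NovaClass.UPF:
        nova_flag = HealthFlag.UNHEALTHY
    else:
        nova_flag = HealthFlag.HEALTHY
    return HealthFlags(
        product_id=product_id,
        flags={
            "DOH": _profile_flag(doh, _HEALTHY_DOH, _UNHEALTHY_DOH),
            "WHO_SEA": _profile_flag(
                whosea, {WHOSEALabel.PERMITTED.value}, {WHOSEALabel.PROHIBITED.value}
            ),
            "HCL": _profile_flag(
                hcl, {HCLLabel.ELIGIBLE.value}, {HCLLabel.NOT_ELIGIBLE.value}
            ),
            "NOVA": nova_flag,
        },
    )


def restrict_to_complete(flags: Iterable[HealthFlags]) -> list[HealthFlags]:
    """Keep only products classifiable by all four systems."""
    return [f for f in flags if f.complete]


def crosstab_2x2(flags: Sequence[HealthFlags], system_a: str, system_b: str) -> CrossTab2x2:
    if not flags:
        raise ValueError("cannot cross-tabulate an empty flag collection")
    n11 = n12 = n21 = n22 = 0
    for f in flags:
        a, b = f.flags[system_a], f.flags[system_b]
        if HealthFlag.NOT_CLASSIFIABLE in (a, b):
            raise ValueError(
                f"product {f.product_id}: flags must be restricted to complete cases"
            )
        if a is HealthFlag.UNHEALTHY:
            if b is HealthFlag.UNHEALTHY:
                n11 += 1
            else:
                n12 += 1
        else:
            if b is HealthFlag.UNHEALTHY:
                n21 += 1
            else:
                n22 += 1
    return CrossTab2x2(labels=(system_a, system_b), n11=n11, n12=n12, n21=n21, n22=n22)


def cohen_kappa(tab: CrossTab2x2) -> KappaResult:
    """Cohen's kappa with marginal-product expected agreement.

    The degenerate case pe = 1 (constant marginals with perfect agreement)
    returns kappa = 1 with ``degenerate=True`` rather than failing.
    """
    n = tab.n
    if n == 0:
        raise ValueError("empty 2x2 table")
    po = (tab.n11 + tab.n22) / n
    pe = ((tab.n11 + tab.n12) * (tab.n11 + tab.n21) + (tab.n21 + tab.n22) * (tab.n12 + tab.n22)) / n**2
    if pe >= 1.0:
        kappa, degenerate = 1.0, True
    else:
        kappa, degenerate = (po - pe) / (1 - pe), False
    return KappaResult(
        po=po,
        pe=pe,
        kappa=kappa,
        percent_agreement=100.0 * po,
        band=interpret_kappa(kappa),
        degenerate=degenerate,
    )


def interpret_kappa(kappa: float) -> KappaBand:
    """Interpretation band; the value is rounded to 2 decimals first."""
    if not -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12:
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    k = round_half_up(kappa, 2)
    if k < 0:
        return KappaBand.NEGATIVE
    if k < 0.01:
        return KappaBand.ZERO
    if k <= 0.20:
        return KappaBand.NONE_TO_SLIGHT
    if k <= 0.40:
        return KappaBand.FAIR
    if k <= 0.60:
        return KappaBand.MODERATE
    if k <= 0.80:
        return KappaBand.SUBSTANTIAL
    return KappaBand.ALMOST_PERFECT


def systems_met_distribution(flags: Sequence[HealthFlags]) -> SystemsMetDistribution:
    """Tally products by how many systems call them healthy (0-4)."""
    counts = [0, 0, 0, 0, 0]
    for f in flags:
        if not f.complete:
            raise ValueError("distribution requires complete cases only")
        counts[f.n_healthy] += 1
    return SystemsMetDistribution(counts=tuple(counts))


def upf_share_among_healthy(flags: Sequence[HealthFlags], system: str) -> Optional[float]:
    """Percent of products healthy under `system` that are NOVA-UPF.

    Returns None when the system classifies no product as healthy.
    """
    healthy = [f for f in flags if f.flags[system] is HealthFlag.HEALTHY]
    if not healthy:
        return None
    n_upf = sum(f.flags["NOVA"] is HealthFlag.UNHEALTHY for f in healthy)
    return 100.0 * n_upf / len(healthy)


def reference_counts() -> dict:
    """The packaged published count tables (agreement and curation)."""
    ref = resources.files("foodprofiler.fixtures") / "reference_counts.json"
    return json.loads(ref.read_text(encoding="utf-8"))


def reference_crosstabs() -> dict[tuple[str, str], CrossTab2x2]:
    tabs = {}
    for key, cells in reference_counts()["pairwise_2x2"].items():
        a, b = key.split("|")
        n11, n12, n21, n22 = cells
        tabs[(a, b)] = CrossTab2x2(labels=(a, b), n11=n11, n12=n12, n21=n21, n22=n22)
    return tabs


def _pairwise_rows(tabs: dict[tuple[str, str], CrossTab2x2]) -> list[dict]:
    rows = []
    for (a, b), tab in tabs.items():
        res = cohen_kappa(tab)
        rows.append(
            {
                "system_a": a,
                "system_b": b,
                "n11": tab.n11,
                "n12": tab.n12,
                "n21": tab.n21,
                "n22": tab.n22,
                "n": tab.n,
                "kappa": res.kappa_3dp,
                "percent_agreement": round_half_up(res.percent_agreement, 2),
                "band": res.band.value,
            }
        )
    return rows


def report_from_crosstabs(
    tabs: dict[tuple[str, str], CrossTab2x2], out_dir: Union[str, Path]
) -> dict[str, Path]:
    """Write the pairwise kappa/percent-agreement matrix (CSV + text)."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = _pairwise_rows(tabs)
    if not rows:
        raise ValueError("no cross-tabulations to report")
    df = pd.DataFrame(rows)
    csv_path = out_dir / "pairwise_agreement.csv"
    df.to_csv(csv_path, index=False)
    txt_path = out_dir / "pairwise_agreement.txt"
    with txt_path.open("w", encoding="utf-8") as fh:
        fh.write("Pairwise agreement (healthy/unhealthy dichotomy)\n\n")
        for r in rows:
            fh.write(
                f"{r['system_a']} vs {r['system_b']}: kappa={r['kappa']:.3f} "
                f"({r['percent_agreement']:.2f}% agreement, {r['band']}, n={r['n']})\n"
            )
    return {"pairwise_csv": csv_path, "pairwise_txt": txt_path}


def build_report(flags: Sequence[HealthFlags], out_dir: Union[str, Path]) -> dict[str, Path]:
    """Compute and write the full agreement report from per-product flags.

    Emits per-system healthy shares, the systems-met distribution, the
    pairwise kappa matrix, and the UPF-share-among-healthy table, each as
    CSV plus a human-readable summary.
    """
    import pandas as pd

    complete = restrict_to_complete(flags)
    if not complete:
        raise ValueError("no complete-case products to report on")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    shares = pd.DataFrame(
        [
            {
                "system": s,
                "n": len(complete),
                "percent_healthy": round_half_up(
                    100.0
                    * sum(f.flags[s] is HealthFlag.HEALTHY for f in complete)
                    / len(complete),
                    1,
                ),
            }
            for s in SYSTEMS
        ]
    )
    paths["shares_csv"] = out_dir / "system_shares.csv"
    shares.to_csv(paths["shares_csv"], index=False)

    dist = systems_met_distribution(complete)
    dist_df = pd.DataFrame(
        {
            "systems_met": list(range(5)),
            "count": list(dist.counts),
            "percent": [round_half_up(p, 1) for p in dist.percentages],
        }
    )
    paths["distribution_csv"] = out_dir / "systems_met_distribution.csv"
    dist_df.to_csv(paths["distribution_csv"], index=False)

    tabs = {}
    pairs = [(a, b) for i, a in enumerate(SYSTEMS) for b in SYSTEMS[i + 1:]]
    for a, b in pairs:
        tabs[(a, b)] = crosstab_2x2(complete, a, b)
    paths.update(report_from_crosstabs(tabs, out_dir))

    upf_rows = []
    for s in ("DOH", "WHO_SEA", "HCL"):
        share = upf_share_among_healthy(complete, s)
        upf_rows.append(
            {
                "system": s,
                "upf_share_among_healthy": None if share is None else round_half_up(share, 1),
            }
        )
    paths["upf_share_csv"] = out_dir / "upf_share_among_healthy.csv"
    pd.DataFrame(upf_rows).to_csv(paths["upf_share_csv"], index=False)

    with (out_dir / "summary.txt").open("w", encoding="utf-8") as fh:
        fh.write(f"Complete-case products: {len(complete)}\n")
        fh.write("Systems-met distribution (0..4): " + ", ".join(map(str, dist.counts)) + "\n")
    paths["summary_txt"] = out_dir / "summary.txt"
    return paths
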