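"""Model-object interface to the inter-chromosomal-effect analysis.

:class:`ICEModel` bundles a carrier case set, its per-case aneuploidy
tallies, and the patient-matched control groups; :meth:`ICEModel.fit` runs
the full weighting + testing pipeline and returns an :class:`ICEResults`
with the pooled comparison, the per-stage rate table, stratified tests, and
a text ``summary()``.

Typical use::

    from iceffect import ICEModel

    model = ICEModel.from_study_tables()     # packaged published tables
    res = model.fit()
    print(res.summary())

or, for a simulated cohort::

    from iceffect.cohort import SimConfig, simulate_cohort

    cohort = simulate_cohort(SimConfig(), seed=1)
    res = ICEModel.from_cohort(cohort).fit()
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .accounting import AneuploidyTally, pool_tallies, stage_table
from .inference import (
    EmbryoLevelResult,
    ICETestResult,
    embryo_level_comparison,
    ice_test,
    stratified_ice,
)
from .karyotype import CarrierCase, CarrierSex, Stage
from .weighting import ControlGroup, WeightedControl, pool_weighted, weight_control

__all__ = ["ICEModel", "ICEResults"]


class ICEModel:
    """Carrier-vs-matched-control aneuploidy comparison.

    Parameters
    ----------
    cases
        The carrier cases (one per PGD cycle).
    carrier_tallies
        Per-case (chromosomes assessed, errors) tallies, keyed by case id.
    control_groups
        Patient-matched control tallies, keyed by matched case id.
    rounding
        Round weighted control expectations half-up to integers (the
        published convention); unrounded expectations are available for
        sensitivity analysis.
    include_compound
        Include the compound-carrier couple (two rearrangements) in
        stratified inference.  It is always included in pooled totals and
        the stage table, whose published sums require it.
    embryo_level
        Optional sample-level inputs (see
        :func:`~iceffect.inference.embryo_level_comparison`) as a mapping
        with ``control`` counts and either carrier counts or an
        ``abnormal_proportion``.
    """

    def __init__(
        self,
        cases: Sequence[CarrierCase],
        carrier_tallies: Mapping[str, AneuploidyTally],
        control_groups: Mapping[str, ControlGroup],
        *,
        rounding: bool = True,
        include_compound: bool = False,
        embryo_level: Mapping | None = None,
    ) -> None:
        self.cases = list(cases)
        missing = [c.case_id for c in self.cases if c.case_id not in carrier_tallies]
        if missing:
            raise ValueError(f"missing carrier tallies for cases {missing}")
        missing = [c.case_id for c in self.cases if c.case_id not in control_groups]
        if missing:
            raise ValueError(f"missing control groups for cases {missing}")
        self.carrier_tallies = dict(carrier_tallies)
        self.control_groups = dict(control_groups)
        self.rounding = rounding
        self.include_compound = include_compound
        self.embryo_level = dict(embryo_level) if embryo_level is not None else None

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_study_tables(cls, **kwargs) -> "ICEModel":
        """Build the model from the packaged published tables."""
        from . import datasets

        cases, tallies = datasets.load_carrier_cases()
        controls = datasets.load_control_groups()
        kwargs.setdefault("embryo_level", datasets.load_embryo_level())
        return cls(cases, tallies, controls, **kwargs)

    @classmethod
    def from_cohort(cls, cohort, which: str = "called", **kwargs) -> "ICEModel":
        """Build the model from a simulated cohort (see
        :func:`~iceffect.cohort.simulate_cohort`)."""
        from .inference import cohort_weighted_controls

        tallies, controls = cohort_weighted_controls(cohort, which)
        return cls(cohort.cases, tallies, controls, **kwargs)

    @classmethod
    def from_tables(cls, case_path, sample_path, control_path, **kwargs) -> "ICEModel":
        """Build the model from TSV files (see :mod:`iceffect.io` for the
        schemas): a case table, a long-format per-sample state table, and a
        control-tally table."""
        from . import io as _io
        from .accounting import tally_case
        from .cohort import slot_of

        cases = _io.read_case_table(case_path)
        samples = _io.read_sample_table(sample_path)
        by_case: dict[str, list] = {}
        for s in samples:
            by_case.setdefault(s.case_id, []).append(s)
        tallies = {
            c.case_id: tally_case(
                by_case.get(c.case_id, []), {slot_of(x) for x in c.excluded}, c
            )
            for c in cases
        }
        controls = _io.read_control_table(control_path)
        return cls(cases, tallies, controls, **kwargs)

    # -- fitting ------------------------------------------------------------

    def fit(self, alpha: float = 0.05, min_chromosomes: int = 1000) -> "ICEResults":
        """Run weighting and testing; returns an :class:`ICEResults`."""
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        weighted = {
            c.case_id: weight_control(
                self.control_groups[c.case_id],
                self.carrier_tallies[c.case_id].chromosomes_assessed,
                rounding=self.rounding,
            )
            for c in self.cases
        }
        pooled_err, pooled_norm = pool_weighted(weighted.values())
        pooled_carrier = pool_tallies(
            [self.carrier_tallies[c.case_id] for c in self.cases]
        )
        raw_err = sum(g.errors for g in self.control_groups.values())
        raw_chrom = sum(g.chromosomes_assessed for g in self.control_groups.values())
        pooled = ice_test(
            pooled_carrier,
            WeightedControl("all", pooled_err, pooled_norm),
            control_rate=raw_err / raw_chrom if raw_chrom else None,
            n_cases=len(self.cases),
        )

        control_tallies = [
            AneuploidyTally(
                chromosomes_assessed=g.chromosomes_assessed,
                errors=g.errors,
                n_samples=g.n_samples,
                case_id=g.matched_case_id,
                stage=g.stage,
            )
            for g in self.control_groups.values()
        ]
        stage_df = stage_table(
            [self.carrier_tallies[c.case_id] for c in self.cases], control_tallies
        )

        kw = dict(
            include_compound=self.include_compound,
            rounding=self.rounding,
            min_chromosomes=min_chromosomes,
        )
        by_class = stratified_ice(
            self.cases, self.carrier_tallies, self.control_groups,
            by=("rearrangement_class",), **kw,
        )
        by_stage = stratified_ice(
            self.cases, self.carrier_tallies, self.control_groups,
            by=("stage",), **kw,
        )
        by_class_stage = stratified_ice(
            self.cases, self.carrier_tallies, self.control_groups,
            by=("rearrangement_class", "stage"), **kw,
        )
        rob_bla_by_sex = stratified_ice(
            self.cases, self.carrier_tallies, self.control_groups,
            by=("carrier_sex",),
            select=lambda c: c.rearrangement_class == "Robertsonian"
            and c.stage is Stage.BLASTOMERE,
            **kw,
        )

        embryo = None
        if self.embryo_level is not None:
            ctrl = self.embryo_level["control"]
            carr = self.embryo_level.get("carrier", {})
            embryo = embryo_level_comparison(
                int(ctrl["abnormal_samples"]),
                int(ctrl["total_samples"]),
                carrier_abnormal=carr.get("abnormal_samples"),
                carrier_total=carr.get("total_samples"),
                carrier_proportion=carr.get("abnormal_proportion"),
            )

        return ICEResults(
            model=self,
            alpha=alpha,
            pooled=pooled,
            stage_rates=stage_df,
            weighted_controls=weighted,
            pooled_expected=(pooled_err, pooled_norm),
            by_class=by_class,
            by_stage=by_stage,
            by_class_stage=by_class_stage,
            robertsonian_blastomere_by_sex=rob_bla_by_sex,
            embryo_level=embryo,
        )


@dataclass
class ICEResults:
    """Fitted results of an :class:`ICEModel`."""

    model: ICEModel
    alpha: float
    #: pooled carrier-vs-weighted-control comparison over all cases.
    pooled: ICETestResult
    #: tidy per-stage rate table for both arms.
    stage_rates: pd.DataFrame
    weighted_controls: dict[str, WeightedControl]
    pooled_expected: tuple[float, float]
    by_class: list[ICETestResult]
    by_stage: list[ICETestResult]
    by_class_stage: list[ICETestResult]
    robertsonian_blastomere_by_sex: list[ICETestResult]
    embryo_level: EmbryoLevelResult | None = None

    def strata_frame(self) -> pd.DataFrame:
        """All stratified comparisons as one tidy frame."""
        rows = []
        for group, results in (
            ("class", self.by_class),
            ("stage", self.by_stage),
            ("class × stage", self.by_class_stage),
            ("Robertsonian blastomere by sex", self.robertsonian_blastomere_by_sex),
        ):
            for r in results:
                rows.append(
                    (
                        group,
                        r.stratum,
                        r.n_cases,
                        r.carrier_errors + r.carrier_normal,
                        r.carrier_errors,
                        r.carrier_rate,
                        r.control_rate,
                        r.relative_risk,
                        r.chi2,
                        r.p_value,
                        r.under_powered,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "grouping",
                "stratum",
                "n_cases",
                "carrier_chromosomes",
                "carrier_errors",
                "carrier_rate",
                "control_rate",
                "relative_risk",
                "chi2",
                "p_value",
                "under_powered",
            ],
        )

    def summary(self) -> str:
        """Human-readable report of the fitted comparisons."""
        lines = []
        p = self.pooled
        top = SimpleTable(
            [
                ["carrier", f"{p.carrier_errors:.0f}", f"{p.carrier_errors + p.carrier_normal:.0f}", f"{p.carrier_rate:.3f}"],
                ["control (weighted)", f"{p.control_expected_errors:.0f}", f"{p.control_expected_errors + p.control_expected_normal:.0f}", f"{p.control_expected_errors / (p.control_expected_errors + p.control_expected_normal):.3f}"],
            ],
            headers=["arm", "errors", "chromosomes", "rate"],
            title="Inter-chromosomal effect: pooled carrier vs weighted control",
        )
        lines.append(top.as_text())
        lines.append(
            f"carrier rate {p.carrier_rate:.3f} vs raw pooled control rate "
            f"{p.control_rate:.3f} ({p.rate_difference * 100:+.1f}% per chromosome "
            f"per sample); RR {p.relative_risk:.3f}; Yates chi2 {p.chi2:.2f}, "
            f"p {p.p_value:.2e}"
        )
        lines.append("")
        sr = self.stage_rates.copy()
        sr["rate"] = (sr["rate"] * 100).map(lambda v: f"{v:.1f}%")
        lines.append(
            SimpleTable(
                sr.values.tolist(),
                headers=list(sr.columns),
                title="Malsegregation of structurally normal chromosomes by stage",
            ).as_text()
        )
        lines.append("")
        sf = self.strata_frame()
        disp = sf.copy()
        for col in ("carrier_rate", "control_rate", "relative_risk", "chi2"):
            disp[col] = disp[col].map(lambda v: f"{v:.3f}")
        disp["p_value"] = disp["p_value"].map(lambda v: f"{v:.2e}")
        disp["under_powered"] = disp["under_powered"].map(lambda v: "*" if v else "")
        lines.append(
            SimpleTable(
                disp.values.tolist(),
                headers=list(disp.columns),
                title=f"Stratified comparisons (alpha = {self.alpha}; * = under-powered)",
            ).as_text()
        )
        if self.embryo_level is not None:
            e = self.embryo_level
            lines.append("")
            lines.append(
                "Embryo-level (cleavage-stage Robertsonian): carrier "
                f"{e.carrier_proportion * 100:.2f}% vs control "
                f"{e.control_proportion * 100:.2f}% abnormal samples; RR "
                f"{e.relative_risk:.3f}"
            )
        return "\n".join(lines)

    def plot_stage_rates(self, ax=None):
        """Grouped bar chart of per-stage malsegregation rates by arm."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        df = self.stage_rates[self.stage_rates["stage"] != "all"]
        piv = df.pivot(index="stage", columns="arm", values="rate")
        piv.plot.bar(ax=ax, rot=0)
        ax.set_ylabel("malsegregation rate per chromosome")
        ax.set_xlabel("biopsy stage")
        ax.set_title("Structurally normal chromosomes: error rate by stage")
        return ax
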