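"""Pre-specified feasibility and acceptability outcomes of the pilot trial.

Feasibility rates are ratios of participant-flow counts (interest, enrolment,
retention, call receipt, app engagement ...) computed from a per-patient
ledger; every reported percentage carries its numerator and denominator so it
can always be re-derived.  Fidelity of the behavioural-support calls is scored
against a 25-item behaviour-change-technique (BCT) checklist, with
double-coding agreement assessed per transcript at an 80% threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FeasibilityOutcome",
    "feasibility_report",
    "recruitment_bias",
    "bct_fidelity",
    "double_code_agreement",
    "N_BCT_ITEMS",
    "AGREEMENT_THRESHOLD",
]

N_BCT_ITEMS = 25
AGREEMENT_THRESHOLD = 80.0  # percent; discrepancies beyond 20% go to consensus


def _round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used in the trial tables)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * math.copysign(1.0, x)


@dataclass(frozen=True)
class FeasibilityOutcome:
    """One feasibility rate: name, raw ratio and conventionally rounded %."""

    name: str
    numerator: int | None
    denominator: int | None

    @property
    def defined(self) -> bool:
        return bool(self.denominator)

    @property
    def percentage(self) -> float | None:
        """Percent rounded half-up to integer; None when undefined."""
        if not self.defined:
            return None
        return _round_half_up(100.0 * self.numerator / self.denominator)

    @property
    def percentage_1dp(self) -> float | None:
        """Percent rounded half-up to one decimal place."""
        if not self.defined:
            return None
        return _round_half_up(100.0 * self.numerator / self.denominator, 1)


def _count(ledger: pd.DataFrame, col: str, mask: pd.Series | None = None) -> int:
    s = ledger[col]
    if mask is not None:
        s = s[mask]
    return int(s.fillna(False).astype(bool).sum())


def feasibility_report(ledger: pd.DataFrame) -> pd.DataFrame:
    """Compute every ledger-derivable feasibility outcome.

    Parameters
    ----------
    ledger : DataFrame
        One row per screened patient with boolean stage columns
        (``sent_letter``, ``willing``, ``sent_pis``, ``consented``,
        ``randomised``, ``followup_any``, ``consent_linkage``,
        ``online_help``, and — for the intervention arm — ``first_call``,
        ``second_call``, ``app_downloaded``, ``app_question_asked``,
        ``app_still_using``) plus an ``arm`` column
        (``intervention``/``control``/NA).

    Returns
    -------
    DataFrame with columns ``outcome, numerator, denominator, percentage,
    percentage_1dp``; rates with a zero denominator are flagged undefined
    (NaN percentages), never reported as 0.
    """
    _check_funnel(ledger)
    interv = ledger["arm"] == "intervention"
    randomised = ledger["randomised"].fillna(False).astype(bool)

    n_letter = _count(ledger, "sent_letter")
    n_willing = _count(ledger, "willing")
    n_pis = _count(ledger, "sent_pis")
    n_rand = int(randomised.sum())
    n_interv = int((interv & randomised).sum())

    outcomes = [
        FeasibilityOutcome("interest", n_willing, n_letter),
        FeasibilityOutcome("enrolment", n_rand, n_pis),
        FeasibilityOutcome(
            "post_randomisation_withdrawal",
            _count(ledger, "withdrew_post_randomisation") if "withdrew_post_randomisation" in ledger else 0,
            n_rand,
        ),
        FeasibilityOutcome("first_call_received", _count(ledger, "first_call", interv), n_interv),
        FeasibilityOutcome("second_call_received", _count(ledger, "second_call", interv), n_interv),
        FeasibilityOutcome("app_downloaded", _count(ledger, "app_downloaded", interv), n_interv),
        FeasibilityOutcome("retention", _count(ledger, "followup_any", randomised), n_rand),
        FeasibilityOutcome(
            "consent_to_linkage",
            _count(ledger, "consent_linkage", randomised) if "consent_linkage" in ledger else n_rand,
            n_rand,
        ),
        FeasibilityOutcome(
            "online_help_required",
            _count(ledger, "online_help", randomised) if "online_help" in ledger else 0,
            n_rand,
        ),
        FeasibilityOutcome(
            "app_still_using",
            _count(ledger, "app_still_using", interv),
            _count(ledger, "app_question_asked", interv),
        ),
    ]
    for col in ("questionnaire", "anthropometrics", "accelerometer"):
        for tp in ("t0", "t1"):
            name = f"{col}_{tp}_completed"
            if name in ledger.columns:
                outcomes.append(
                    FeasibilityOutcome(name, _count(ledger, name, randomised), n_rand)
                )

    return pd.DataFrame(
        {
            "outcome": [o.name for o in outcomes],
            "numerator": [o.numerator for o in outcomes],
            "denominator": [o.denominator for o in outcomes],
            "percentage": [o.percentage if o.defined else np.nan for o in outcomes],
            "percentage_1dp": [o.percentage_1dp if o.defined else np.nan for o in outcomes],
        }
    )


_FUNNEL_ORDER = ["sent_letter", "willing", "sent_pis", "consented", "randomised"]


def _check_funnel(ledger: pd.DataFrame) -> None:
    prev = None
    for col in _FUNNEL_ORDER:
        if col not in ledger.columns:
            raise ValueError(f"ledger missing stage column {col!r}")
        n = _count(ledger, col)
        if prev is not None and n > prev[1]:
            raise ValueError(
                f"funnel monotonicity violated: {col} ({n}) > {prev[0]} ({prev[1]})"
            )
        prev = (col, n)


def recruitment_bias(sample: pd.DataFrame, site: pd.DataFrame) -> pd.DataFrame:
    """Side-by-side n (%) comparison of the recruited sample vs the site.

    Both inputs are long tables with columns ``variable, category, n``;
    ``site`` additionally needs a per-variable total consistent with its
    subgroup sums (validated).  Percentages use the round-half-up convention.
    """
    for name, df in (("sample", sample), ("site", site)):
        missing = {"variable", "category", "n"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns {sorted(missing)}")
    site_totals = site.groupby("variable")["n"].sum()
    if "total" in site.attrs:
        for var, tot in site_totals.items():
            if tot != site.attrs["total"]:
                raise ValueError(
                    f"site subgroup counts for {var!r} sum to {tot}, "
                    f"stated total is {site.attrs['total']}"
                )
    sample_totals = sample.groupby("variable")["n"].sum()

    merged = sample.merge(
        site, on=["variable", "category"], how="outer", suffixes=("_sample", "_site")
    ).fillna({"n_sample": 0, "n_site": 0})
    merged["pct_sample"] = [
        _round_half_up(100.0 * n / sample_totals[v]) if sample_totals[v] else np.nan
        for v, n in zip(merged["variable"], merged["n_sample"])
    ]
    merged["pct_site"] = [
        _round_half_up(100.0 * n / site_totals[v]) if site_totals[v] else np.nan
        for v, n in zip(merged["variable"], merged["n_site"])
    ]
    return merged


def _coding_matrix(codings: pd.DataFrame) -> np.ndarray:
    cols = [c for c in codings.columns if c.startswith("bct_")]
    if len(cols) != N_BCT_ITEMS:
        raise ValueError(f"expected {N_BCT_ITEMS} bct_* columns, got {len(cols)}")
    mat = codings[sorted(cols)].to_numpy()
    if not np.isin(mat, (0, 1)).all():
        raise ValueError("BCT indicators must be binary")
    return mat


def bct_fidelity(codings: pd.DataFrame) -> tuple[pd.Series, float]:
    """Percent of the 25 required BCTs delivered, per call and overall.

    ``codings`` has one row per coded call with columns ``call_id`` and
    ``bct_01`` .. ``bct_25`` (1 = delivered).  Returns the per-call
    percentages (indexed by call_id) and their mean.
    """
    if len(codings) == 0:
        raise ValueError("need at least one coding record")
    mat = _coding_matrix(codings)
    per_call = pd.Series(
        100.0 * mat.sum(axis=1) / N_BCT_ITEMS, index=codings["call_id"].to_numpy()
    )
    return per_call, float(per_call.mean())


def double_code_agreement(
    coder_a: pd.DataFrame, coder_b: pd.DataFrame
) -> pd.DataFrame:
    """Inter-coder agreement on the BCT checklist, per double-coded transcript.

    Agreement is the percent of the 25 indicators on which the coders match;
    transcripts where it falls below 80% (i.e. discrepancy exceeds 20%) are
    flagged for consensus discussion.
    """
    a = coder_a.sort_values("call_id").reset_index(drop=True)
    b = coder_b.sort_values("call_id").reset_index(drop=True)
    if not (a["call_id"].to_numpy() == b["call_id"].to_numpy()).all():
        raise ValueError("coders must cover the same calls")
    ma, mb = _coding_matrix(a), _coding_matrix(b)
    agreement = 100.0 * (ma == mb).sum(axis=1) / N_BCT_ITEMS
    return pd.DataFrame(
        {
            "call_id": a["call_id"],
            "agreement_pct": agreement,
            "needs_consensus": agreement < AGREEMENT_THRESHOLD,
        }
    )
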