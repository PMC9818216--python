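"""Classify star-network centers as common, disease-specific, or severity signatures.

A center's membership flags record whether it anchored a four-layer star in
each of the four subject-subset analyses (all subjects, Ctrl-LC, Ctrl-HCC,
LC-HCC).  The decision rules, applied in order:

1. Present in both Ctrl-LC and Ctrl-HCC (with or without the all-subjects
   analysis): **Common** - the center distinguishes each disease cohort
   from healthy controls.
2. Ctrl-LC only: **LCSpecific**.
3. Ctrl-HCC only: **HCCSpecific**.
4. All-subjects only: **CommonAllOnly** when the control cohort's mean of
   the center is strictly the extreme (minimum or maximum) of the three
   cohort means, with both disease cohorts on the same side - the weaker,
   direction-based evidence class for a shared disease signature; otherwise
   **Unclassified**.
5. Anything else: **Unclassified**.

Severity association (membership in the LC-HCC analysis) is an orthogonal
flag: a center can be both a common signature and severity-associated.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .network import FeatureRef, StarNetwork

LABELS = ("Common", "CommonAllOnly", "LCSpecific", "HCCSpecific", "Unclassified")

#: Printed-table vocabulary <-> internal labels.
PRINTED_LABEL = {
    "Common": "Common",
    "CommonAllOnly": "Common *",
    "LCSpecific": "LC specific",
    "HCCSpecific": "HCC specific",
    "Unclassified": "-",
}
_FROM_PRINTED = {v: k for k, v in PRINTED_LABEL.items()}


@dataclass(frozen=True)
class Membership:
    """Star-membership flags of one center across the four subset analyses."""

    all_subjects: bool = False
    ctrl_lc: bool = False
    ctrl_hcc: bool = False
    lc_hcc: bool = False


@dataclass(frozen=True)
class SignatureCall:
    """One center's classified signature."""

    center: str
    label: str
    severity: bool
    direction_note: str = ""


def classify(membership: Membership, cohort_means: Mapping[str, float] | None = None,
             center: str = "") -> SignatureCall:
    """Apply the signature decision rules to one center's membership flags.

    ``cohort_means`` (Ctrl/LC/HCC -> mean of the center feature) is only
    consulted on the all-subjects-only branch and must be provided when
    that branch is reachable.
    """
    m = membership
    severity = m.lc_hcc
    note = ""
    if m.ctrl_lc and m.ctrl_hcc:
        label = "Common"
    elif m.ctrl_lc:
        label = "LCSpecific"
    elif m.ctrl_hcc:
        label = "HCCSpecific"
    elif m.all_subjects:
        if cohort_means is None:
            raise ValueError(
                f"center {center!r}: cohort means required to resolve an "
                "all-subjects-only membership"
            )
        ctrl = cohort_means["Ctrl"]
        lc, hcc = cohort_means["LC"], cohort_means["HCC"]
        if ctrl < min(lc, hcc):
            label = "CommonAllOnly"
            note = "Ctrl mean lowest; LC and HCC both elevated"
        elif ctrl > max(lc, hcc):
            label = "CommonAllOnly"
            note = "Ctrl mean highest; LC and HCC both reduced"
        else:
            label = "Unclassified"
    else:
        label = "Unclassified"
    return SignatureCall(center=center, label=label, severity=severity,
                         direction_note=note)


def membership_matrix(stars_by_subset: Mapping[str, Sequence[StarNetwork]]
                      ) -> dict[FeatureRef, Membership]:
    """Collect per-center membership flags from the four subset star lists."""
    centers: set[FeatureRef] = set()
    present: dict[str, set[FeatureRef]] = {}
    for subset, stars in stars_by_subset.items():
        present[subset] = {s.center for s in stars}
        centers |= present[subset]
    return {
        c: Membership(
            all_subjects=c in present.get("ALL", set()),
            ctrl_lc=c in present.get("CTRL_LC", set()),
            ctrl_hcc=c in present.get("CTRL_HCC", set()),
            lc_hcc=c in present.get("LC_HCC", set()),
        )
        for c in sorted(centers)
    }


def classify_all(memberships: Mapping[FeatureRef, Membership],
                 cohort_means: Mapping[FeatureRef, Mapping[str, float]] | None = None,
                 ) -> list[SignatureCall]:
    """Classify every center; order of input does not affect the calls."""
    calls = []
    for ref, m in memberships.items():
        means = None if cohort_means is None else cohort_means.get(ref)
        calls.append(classify(m, means, center=ref[1]))
    return calls


def calls_to_frame(calls: Sequence[SignatureCall],
                   memberships: Mapping[FeatureRef, Membership] | None = None
                   ) -> pd.DataFrame:
    """Report table in the printed summary layout (Yes/- flags + label)."""
    rows = []
    mm = {ref[1]: m for ref, m in (memberships or {}).items()}
    for c in calls:
        m = mm.get(c.center)
        rows.append({
            "center": c.center,
            "all_subjects": _yes(m.all_subjects) if m else "",
            "ctrl_lc": _yes(m.ctrl_lc) if m else "",
            "ctrl_hcc": _yes(m.ctrl_hcc) if m else "",
            "signature": PRINTED_LABEL[c.label],
            "severity_lc_hcc": _yes(c.severity),
        })
    cols = ["center", "all_subjects", "ctrl_lc", "ctrl_hcc", "signature",
            "severity_lc_hcc"]
    return pd.DataFrame(rows, columns=cols)


def _yes(flag: bool) -> str:
    return "Yes" if flag else "-"


# ---------------------------------------------------------------------------
# Published-summary reproduction
# ---------------------------------------------------------------------------

def load_published_membership() -> pd.DataFrame:
    """The packaged transcription of the published 39-center summary table.

    Columns: center, layer, the four membership flags (0/1), the printed
    signature label, and - for the centers whose classification needs a
    direction check - the three cohort means of the feature.
    """
    with resources.files("gutliver.data").joinpath("published_membership.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def reproduce_published_table(fixture: pd.DataFrame | None = None) -> pd.DataFrame:
    """Re-derive every printed signature label from the membership flags.

    Returns the fixture with ``computed_label`` and ``computed_severity``
    columns alongside the printed ones; agreement on all rows is the
    correctness check for the rule set.
    """
    df = load_published_membership() if fixture is None else fixture.copy()
    computed = []
    for _, row in df.iterrows():
        m = Membership(
            all_subjects=bool(row["all_subjects"]),
            ctrl_lc=bool(row["ctrl_lc"]),
            ctrl_hcc=bool(row["ctrl_hcc"]),
            lc_hcc=bool(row["lc_hcc"]),
        )
        means = None
        if pd.notna(row.get("ctrl_mean")):
            means = {"Ctrl": row["ctrl_mean"], "LC": row["lc_mean"],
                     "HCC": row["hcc_mean"]}
        computed.append(classify(m, means, center=row["center"]))
    df["computed_label"] = [PRINTED_LABEL[c.label] for c in computed]
    df["computed_severity"] = [_yes(c.severity) for c in computed]
    return df
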