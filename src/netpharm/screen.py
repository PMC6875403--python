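"""ADME screening of herb ingredients.

Candidate compounds of a multi-herb formula are selected by two absorption /
drug-likeness surrogates computed upstream (e.g. by TCMSP): oral
bioavailability (OB, a percentage) and drug-likeness (DL, a dimensionless
index in [0, 1]).  The conventional cutoffs are OB >= 30% jointly with
DL >= 0.18.  Compounds failing the cutoffs but with well-documented
pharmacological activity (the classic examples being psoralen and angelicin)
can be rescued through an explicit whitelist flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Herb codes of the five-herb formula this pipeline was built around.
KBL_HERBS: tuple[str, ...] = ("BGZ", "BZ", "FJ", "WM", "GC")


@dataclass(frozen=True)
class CompoundRecord:
    """One herb ingredient, the unit of ADME screening.

    Parameters
    ----------
    compound_id
        Unique identifier of the compound.
    name
        Human-readable compound name.
    herbs
        Codes of the herbs the compound occurs in; non-empty.
    ob
        Oral bioavailability in percent, >= 0.
    dl
        Drug-likeness index in [0, 1].
    whitelisted
        Literature-override flag: a whitelisted compound is kept as a
        candidate regardless of its OB/DL values.
    """

    compound_id: str
    name: str
    herbs: frozenset[str]
    ob: float
    dl: float
    whitelisted: bool = False

    def __post_init__(self) -> None:
        if not self.herbs:
            raise ValueError(f"compound {self.compound_id!r}: herbs must be non-empty")
        if self.ob < 0:
            raise ValueError(f"compound {self.compound_id!r}: ob must be >= 0, got {self.ob}")
        if not 0.0 <= self.dl <= 1.0:
            raise ValueError(f"compound {self.compound_id!r}: dl must be in [0, 1], got {self.dl}")


@dataclass(frozen=True)
class ScreenConfig:
    """Cutoffs for candidate-compound selection.

    Both cutoffs must hold jointly.  ``inclusive`` controls the comparison
    operator: ``True`` (default) uses >=, ``False`` uses strict >.
    """

    ob_min: float = 30.0
    dl_min: float = 0.18
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.ob_min < 0:
            raise ValueError(f"ob_min must be >= 0, got {self.ob_min}")
        if not 0.0 <= self.dl_min <= 1.0:
            raise ValueError(f"dl_min must be in [0, 1], got {self.dl_min}")

    def passes(self, record: CompoundRecord) -> bool:
        """Whether ``record`` clears both cutoffs (whitelist ignored)."""
        if self.inclusive:
            return record.ob >= self.ob_min and record.dl >= self.dl_min
        return record.ob > self.ob_min and record.dl > self.dl_min


def screen_compounds(
    records: list[CompoundRecord], config: ScreenConfig | None = None
) -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """Partition compounds into ADME candidates and rejects.

    A record is a candidate iff it clears both OB/DL cutoffs or carries the
    whitelist flag.  Input order is preserved in both output lists, and the
    two lists partition the input exactly.

    Returns
    -------
    (candidates, rejected)
    """
    config = config or ScreenConfig()
    candidates: list[CompoundRecord] = []
    rejected: list[CompoundRecord] = []
    for rec in records:
        if config.passes(rec) or rec.whitelisted:
            candidates.append(rec)
        else:
            rejected.append(rec)
    return candidates, rejected


def per_herb_counts(
    candidates: list[CompoundRecord], herbs: tuple[str, ...] = KBL_HERBS
) -> dict[str, int]:
    """Count candidate compounds per herb.

    A compound belonging to k herbs contributes 1 to each of its k herbs, so
    the counts sum to at least the number of candidates.

    Raises
    ------
    ValueError
        If a candidate references a herb code not in ``herbs``.
    """
    counts: dict[str, int] = {h: 0 for h in herbs}
    known = set(herbs)
    for rec in candidates:
        unknown = rec.herbs - known
        if unknown:
            raise ValueError(
                f"compound {rec.compound_id!r}: unknown herb code(s) {sorted(unknown)}"
            )
        for h in rec.herbs:
            counts[h] += 1
    return counts


def shared_compounds(candidates: list[CompoundRecord]) -> list[CompoundRecord]:
    """Candidates distributed in more than one herb, in input order."""
    return [rec for rec in candidates if len(rec.herbs) >= 2]


def screen_summary(
    records: list[CompoundRecord],
    candidates: list[CompoundRecord],
    config: ScreenConfig,
    herbs: tuple[str, ...] = KBL_HERBS,
) -> dict:
    """Machine-readable accounting of a screening run."""
    n_pass = sum(1 for r in records if config.passes(r))
    n_rescued = sum(1 for r in candidates if r.whitelisted and not config.passes(r))
    return {
        "n_input": len(records),
        "n_pass_filter": n_pass,
        "n_whitelisted_rescues": n_rescued,
        "n_candidates": len(candidates),
        "per_herb_counts": per_herb_counts(candidates, herbs),
        "n_shared": len(shared_compounds(candidates)),
    }
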