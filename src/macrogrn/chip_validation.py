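"""Agreement between a GRN's predicted regulon and a ChIP-derived target set.

The headline number is the fraction of a TF's predicted targets that are
supported by ChIP (the precision of the prediction); the reverse fraction
(recall of the ChIP set) is reported alongside, since either direction
may be the one a reader wants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .containers import StrainGRN
from .exceptions import UsageError


@dataclass(frozen=True)
class TargetRecovery:
    tf: str
    strain: str
    n_predicted: int
    n_chip: int
    n_overlap: int
    recovery_fraction: float  # |predicted & chip| / |predicted|
    chip_fraction: float  # |predicted & chip| / |chip|


def target_recovery(
    grn: StrainGRN, tf: str, chip_targets: Iterable[str]
) -> TargetRecovery:
    """Overlap statistics between predicted and ChIP targets of one TF.

    Raises a usage error when the TF has no predicted targets in the GRN
    (the fraction would be undefined, not zero) or when the ChIP set is
    empty.
    """
    chip = frozenset(chip_targets)
    if not chip:
        raise UsageError("ChIP target set is empty")
    predicted = grn.targets_of(tf)
    if not predicted:
        raise UsageError(
            f"TF {tf!r} has no predicted targets in the {grn.strain} GRN; "
            "recovery is undefined"
        )
    overlap = predicted & chip
    return TargetRecovery(
        tf=tf,
        strain=grn.strain,
        n_predicted=len(predicted),
        n_chip=len(chip),
        n_overlap=len(overlap),
        recovery_fraction=len(overlap) / len(predicted),
        chip_fraction=len(overlap) / len(chip),
    )


def write_validation_table(records: Sequence[TargetRecovery], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "tf\tstrain\tn_predicted\tn_chip\tn_overlap\tprecision\trecall\n"
        )
        for r in records:
            fh.write(
                f"{r.tf}\t{r.strain}\t{r.n_predicted}\t{r.n_chip}\t"
                f"{r.n_overlap}\t{r.recovery_fraction:.6g}\t{r.chip_fraction:.6g}\n"
            )
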