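"""Climate-predictor preparation: rescaling and collinearity screening.

The modeling grid is usually coarser than the climate product; ``rescale_stack``
aggregates by block means.  ``select_variables`` screens the candidate set
down to a low-correlation subset (default pairwise |Pearson r| cutoff 0.6)
by greedy elimination, with a ``preferred`` list standing in for the
judgment-based choice among equally acceptable candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grid import ClimateStack, GridSpec

__all__ = ["VariableSelection", "rescale_stack", "select_variables"]


@dataclass
class VariableSelection:
    """Outcome of collinearity screening.

    ``dropped`` pairs each removed variable with the partner whose
    correlation triggered the removal.
    """

    kept: list[str]
    dropped: list[tuple[str, str]] = field(default_factory=list)
    cutoff: float = 0.6


def rescale_stack(stack: ClimateStack, target: GridSpec) -> ClimateStack:
    """Aggregate a stack to a coarser grid by block (arithmetic) means.

    The target cell size must be an integer multiple of the source's, and
    the source grid must tile exactly into target cells.  NaN source cells
    are ignored in each block mean.
    """
    src = stack.grid
    factor = target.cell_size / src.cell_size
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"target cell size {target.cell_size} is not an integer multiple "
            f"of source cell size {src.cell_size}"
        )
    f = int(round(factor))
    if f == 1:
        if src.shape != target.shape:
            raise ValueError("same resolution but different grid shapes")
        return ClimateStack(target, list(stack.variables), stack.values.copy(), stack.scenario)
    if src.n_rows != target.n_rows * f or src.n_cols != target.n_cols * f:
        raise ValueError("source grid does not tile exactly into the target grid")
    blocks = stack.values.reshape(stack.n_variables, target.n_rows, f, target.n_cols, f)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        values = np.nanmean(blocks, axis=(2, 4))
    return ClimateStack(target, list(stack.variables), values, stack.scenario)


def select_variables(
    stack: ClimateStack,
    cutoff: float = 0.6,
    preferred: Sequence[str] | None = None,
) -> VariableSelection:
    """Greedy low-correlation subset selection.

    While any kept pair has |Pearson r| strictly above ``cutoff``, the
    worst pair is found and the member with the larger mean absolute
    correlation to all other kept variables is dropped — unless it is in
    ``preferred`` and its partner is not.  Zero-variance variables are
    dropped first with a warning.  Ties break by variable order.
    """
    if stack.n_variables < 2:
        raise ValueError("need at least 2 variables")
    if stack.grid.n_cells < 3:
        raise ValueError("need at least 3 cells to estimate correlations")
    preferred = set(preferred or ())
    names = list(stack.variables)
    table = stack.table()

    dropped: list[tuple[str, str]] = []
    sds = table.std(axis=0)
    for i in np.nonzero(sds == 0)[0][::-1]:
        warnings.warn(f"variable {names[i]!r} is constant; dropped", stacklevel=2)
        dropped.append((names[i], names[i]))
        names = names[:i] + names[i + 1 :]
    if len(names) < 2:
        return VariableSelection(names, dropped, cutoff)

    kept = list(names)
    while len(kept) > 1:
        sub = stack.table(kept)
        corr = np.abs(np.corrcoef(sub, rowvar=False))
        np.fill_diagonal(corr, 0.0)
        worst = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[worst] <= cutoff:
            break
        i, j = sorted(worst)
        a, b = kept[i], kept[j]
        mean_abs = corr.sum(axis=0) / (len(kept) - 1)
        # prefer to drop the variable more entangled with everything else,
        # unless the preferred list protects it
        if a in preferred and b not in preferred:
            victim = b
        elif b in preferred and a not in preferred:
            victim = a
        elif mean_abs[j] > mean_abs[i]:
            victim = b
        elif mean_abs[i] > mean_abs[j]:
            victim = a
        else:
            victim = b  # tie: keep the earlier variable
        partner = a if victim == b else b
        dropped.append((victim, partner))
        kept.remove(victim)
    return VariableSelection(kept, dropped, cutoff)
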