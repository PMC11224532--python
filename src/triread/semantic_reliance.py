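"""Semantic reliance (SR): lesion-based division-of-labour measurement.

Semantic access from print runs over two routes: the direct
print-to-meaning route (OS: orthography -> hidden -> semantics) and the
phonologically mediated route (OPS: orthography -> hidden -> phonology
-> ... -> semantics).  To quantify how much a trained model relies on
each, one route is severed at a time (all connection matrices on it set
to zero) and the mean semantic SSE over the training set is recorded
while reading through the surviving route.  Reciprocal SSEs act as
pathway contributions, and

    SR = (1 / SSE_via_OS) / (1 / SSE_via_OS + 1 / SSE_via_OPS)

is the proportional contribution of the direct meaning route: 0.5 when
the routes are equally good, near 0 for a print-to-sound reader, near 1
for a print-to-meaning reader.  Attractor and context groups stay
intact under both lesions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import netcore
from .errors import TriReadError
from .evaluation import phon_sse

__all__ = [
    "LesionSpec",
    "SRScore",
    "PATHWAY_GROUPS",
    "lesion_network",
    "pathway_sse",
    "compute_sr",
    "measure_sr",
]

#: Connection groups removed by each lesion.
PATHWAY_GROUPS: dict[str, tuple[str, ...]] = {
    "OPS": ("orthography->hidden_op", "hidden_op->phonology"),
    "OS": ("orthography->hidden_os", "hidden_os->semantics"),
}

#: Epsilon floor applied to SSEs before taking reciprocals.
SSE_FLOOR = 1e-6


@dataclass(frozen=True)
class LesionSpec:
    """Which orthographic route to sever; damage mode is zeroing every
    connection matrix on the route."""

    pathway: str

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAY_GROUPS:
            raise TriReadError(
                f"unknown pathway {self.pathway!r}; lesions sever one of "
                f"{sorted(PATHWAY_GROUPS)} (a double lesion would leave "
                "no route for SR)")


@dataclass(frozen=True)
class SRScore:
    """Pathway SSEs and the derived semantic-reliance ratio."""

    sse_via_os: float   # semantic SSE with the OPS route lesioned
    sse_via_ops: float  # semantic SSE with the OS route lesioned

    @property
    def contribution_os(self) -> float:
        return 1.0 / max(self.sse_via_os, SSE_FLOOR)

    @property
    def contribution_ops(self) -> float:
        return 1.0 / max(self.sse_via_ops, SSE_FLOOR)

    @property
    def sr(self) -> float:
        return self.contribution_os / (self.contribution_os
                                       + self.contribution_ops)


def lesion_network(weights: netcore.WeightSet,
                   lesion: LesionSpec | str) -> netcore.WeightSet:
    """A copy of the weights with every matrix on the lesioned route set
    to zero; all other groups (including attractors and the context
    path) untouched.  The original weights are not modified."""
    if isinstance(lesion, str):
        lesion = LesionSpec(lesion)
    ws = weights.copy()
    for group in PATHWAY_GROUPS[lesion.pathway]:
        ws.zero_group(group)
    ws.meta = dict(ws.meta, lesion=lesion.pathway)
    return ws


def pathway_sse(weights: netcore.WeightSet, lexicon,
                lesion: LesionSpec | str | None = None) -> float:
    """Mean semantic SSE over all lexicon words read through a (possibly
    lesioned) network: each word is presented at orthography for the
    standard 12-step reading trial (context clamped for homophones,
    since the measured target is a specific meaning) and the SSE is
    taken at the trial's error-injection window."""
    from .training import READING_TASKS, CompiledLexicon
    compiled = lexicon if isinstance(lexicon, CompiledLexicon) \
        else CompiledLexicon(lexicon, dtype=weights.dtype)
    ws = lesion_network(weights, lesion) if lesion is not None else weights
    task = READING_TASKS["OS"]
    sses = []
    for i in range(len(compiled)):
        tr = netcore.forward_trial(ws, compiled.trial(i, task))
        sses.append(phon_sse(tr, compiled.sem[i], task.window,
                             layer="semantics"))
    return float(np.mean(sses))


def compute_sr(sse_via_os: float, sse_via_ops: float,
               eps: float = SSE_FLOOR) -> float:
    """SR from the two lesioned-pathway SSEs (reciprocal-contribution
    ratio); SSEs are floored at ``eps`` before inversion."""
    for name, v in (("sse_via_os", sse_via_os),
                    ("sse_via_ops", sse_via_ops)):
        if not np.isfinite(v) or v < 0:
            raise FloatingPointError(f"{name} must be finite and >= 0")
    c_os = 1.0 / max(sse_via_os, eps)
    c_ops = 1.0 / max(sse_via_ops, eps)
    return c_os / (c_os + c_ops)


def measure_sr(weights: netcore.WeightSet, lexicon) -> SRScore:
    """Lesion each orthographic route in turn and form the SR score.

    The input weights are left untouched (lesions operate on copies).
    """
    sse_via_os = pathway_sse(weights, lexicon, "OPS")
    sse_via_ops = pathway_sse(weights, lexicon, "OS")
    return SRScore(sse_via_os=sse_via_os, sse_via_ops=sse_via_ops)
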