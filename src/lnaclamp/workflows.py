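"""End-to-end design workflows tying the per-module operations together.

These are the pipelines a user actually runs: from an annotated alignment to
(1) the degenerate LNA forward primer with its Tm range, and (2) the per-host
clamping oligos with screening and the recommended clamp-annealing step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .alignio import Alignment
from .clamp_design import ClampDesign, design_clamp, screen_cross_reactivity
from .oligo import Oligo
from .primer_design import DEFAULT_CONFIG, DesignConfig, degenerate_consensus, plan_lna
from .profiling import DiscriminatingSite, column_profiles, discriminating_positions, group_by_identity
from .thermo import DEFAULT_CONDITIONS, Conditions, TmEstimate, tm_oligo


@dataclass(frozen=True)
class PrimerDesignResult:
    dna_primer: Oligo
    lna_primer: Oligo
    discriminating: tuple[DiscriminatingSite, ...]
    tm: TmEstimate

    def report(self) -> str:
        lna = ",".join(map(str, self.lna_primer.lna_positions)) or "none"
        return "\n".join(
            [
                f"degenerate DNA primer : {self.dna_primer.bases}",
                f"LNA primer            : {self.lna_primer.annotated()}",
                f"LNA positions (1-based): {lna}",
                (
                    f"Tm (median over {self.tm.n_expansions} expansions): "
                    f"{self.tm.tm:.1f} C (range {self.tm.tm_min:.1f}-{self.tm.tm_max:.1f})"
                ),
            ]
        )


def design_forward_primer(
    aln: Alignment,
    config: DesignConfig = DEFAULT_CONFIG,
    conditions: Conditions = DEFAULT_CONDITIONS,
    name: str = "forward_primer",
) -> PrimerDesignResult:
    """Degenerate consensus over targets + LNA at fungus/plant-discriminating
    positions, with the degenerate-expansion Tm range."""
    target_profiles = column_profiles(aln, "target")
    nontarget = {
        g: column_profiles(aln, g) for g in aln.groups() if g.startswith("nontarget")
    }
    dna = degenerate_consensus(
        target_profiles, config.minor_freq_threshold, name=f"{name} DNA"
    )
    sites = discriminating_positions(
        target_profiles, nontarget, config.target_purity, config.nontarget_purity
    )
    lna = plan_lna(dna, sites, config, name=f"{name} LNA")
    return PrimerDesignResult(
        dna_primer=dna,
        lna_primer=lna,
        discriminating=tuple(sites),
        tm=tm_oligo(lna, conditions),
    )


def design_host_clamps(
    aln: Alignment,
    reverse_primer_anchor: int,
    config: DesignConfig = DEFAULT_CONFIG,
    conditions: Conditions = DEFAULT_CONDITIONS,
) -> dict[str, ClampDesign]:
    """One screened clamp per host sequence type.

    Host (non-target) rows are partitioned into identity types over the
    designable window; each type gets a clamp, screened for exact
    complementarity against the target rows.  Keys are ``"<type letter>
    (<first member id>)"`` in order of first appearance.
    """
    from dataclasses import replace as _replace

    hosts = aln.select("nontarget")
    targets = aln.select("target")
    window = (max(1, reverse_primer_anchor - 24), min(aln.n_cols, reverse_primer_anchor + 1))
    types = group_by_identity(hosts, window=window)
    target_profiles = column_profiles(targets)
    out: dict[str, ClampDesign] = {}
    for label, members in types.items():
        sub = Alignment(tuple(r for r in hosts.records if r.id in set(members)))
        design = design_clamp(
            sub,
            reverse_primer_anchor,
            target_profiles,
            config,
            conditions,
            host_type=f"{label} ({members[0]})",
        )
        screen = screen_cross_reactivity(design, targets)
        out[design.host_type] = _replace(design, screen=screen)
    return out
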