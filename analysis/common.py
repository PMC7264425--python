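"""Shared study definition for the numbered analysis scripts.

One synthetic two-genotype experiment stands in for the wild-type vs.
demethylase-mutant comparison: 144 NLR-like genes, of which 50 carry a
+40-pp CG hypermethylation effect at the 500-bp upstream window, 10 carry a
-15-pp CG effect at the 200-bp window, and 15 carry a +10-pp CG effect in
the gene body.  Twenty of the hypermethylated genes are also repressed
(ratio 0.5) and fifteen unrelated genes induced (ratio 1.5) in the mutant's
expression table.  Scripts either read the files script 01 wrote under
scratch/study/ or regenerate the identical study from the seed.
"""

from __future__ import annotations

from pathlib import Path

from nlr_methylome.simulate import (
    SimulationConfig,
    SyntheticStudy,
    simulate_annotation,
    simulate_genome,
    simulate_study,
)

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

STUDY_SEED = 42

N_UPR500_HYPER = 50
N_UPR200_HYPO = 10
N_GBR_HYPER = 15
N_REPRESSED = 20
N_INDUCED = 15


def study_config(seed: int = STUDY_SEED) -> SimulationConfig:
    probe = SimulationConfig(seed=seed)
    genes, _ = simulate_annotation(probe, simulate_genome(probe))
    ids = [g.gene_id for g in genes]
    planted_dm = (
        [(g, "UPR500", "CG", 40.0) for g in ids[:N_UPR500_HYPER]]
        + [(g, "UPR200", "CG", -15.0) for g in ids[N_UPR500_HYPER : N_UPR500_HYPER + N_UPR200_HYPO]]
        + [(g, "GBR", "CG", 10.0) for g in ids[-N_GBR_HYPER:]]
    )
    planted_expr = [(g, 0.5) for g in ids[:N_REPRESSED]] + [
        (g, 1.5) for g in ids[N_UPR500_HYPER + N_UPR200_HYPO : N_UPR500_HYPER + N_UPR200_HYPO + N_INDUCED]
    ]
    return SimulationConfig(seed=seed, planted_dm=planted_dm, planted_expr=planted_expr)


def get_study(seed: int = STUDY_SEED) -> SyntheticStudy:
    """Regenerate the study deterministically from its seed."""
    return simulate_study(study_config(seed))


def planted_sets(config: SimulationConfig) -> dict[str, set]:
    return {
        "dm": {(g, k, c) for g, k, c, _ in config.planted_dm},
        "expr_down": {g for g, r in config.planted_expr if r < 1},
        "expr_up": {g for g, r in config.planted_expr if r > 1},
    }
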