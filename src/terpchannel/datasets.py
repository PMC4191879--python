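"""Bundled published datasets.

The squalene-hopene cyclase (1SQC) active-site mutant table ships with the
package: per-intermediate MM/GBSA docking scores of the hopene-channel
cations against the Y609C/Y609L/Y609S and L607K mutants, expressed relative
to the wild-type scores (kcal/mol; ``NP`` where no docking pose could be
obtained). These experimental-computational reference values drive the
mutant-classification analysis.
"""

from __future__ import annotations

from importlib import resources

from .channels import ChannelLibrary, default_library
from .scores import ScoreTable, read_scores_csv

__all__ = ["load_shc_mutant_scores", "SHC_MUTANTS", "SHC_WILD_TYPE"]

SHC_WILD_TYPE = "1SQC-wild"
SHC_MUTANTS = ("1SQC-Y609C", "1SQC-Y609L", "1SQC-Y609S", "1SQC-L607K")


def load_shc_mutant_scores(library: ChannelLibrary | None = None) -> ScoreTable:
    """Relative-mode score table for the 1SQC mutants (and a wild-type row
    of zeros)."""
    lib = library or default_library()
    with resources.as_file(
        resources.files("terpchannel.data").joinpath("shc_mutant_relative_scores.csv")
    ) as p:
        return read_scores_csv(p, lib, mode="relative")
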