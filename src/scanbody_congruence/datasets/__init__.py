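"""Bundled example data.

``load_ios_study_cells`` returns the per-cell descriptive statistics
(mean, SD, median, quartiles of the absolute mesh-to-library deviation, um,
over 10 model replicates) from a published five-scanner benchmark of
intraoral scanners capturing six implant scanbodies (S1-S6) on a fully
edentulous maxillary cast.  It is the canonical input for the balanced
two-level reanalysis: with 10 replicates per cell the design is balanced,
so scanner-level estimates and contrasts are exact functions of these cell
means.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_ios_study_cells"]


def load_ios_study_cells() -> pd.DataFrame:
    """Cell-level summary table: scanner, sb, n, mean, sd, median, q1, q3."""
    with resources.files(__package__).joinpath("ios_study_cells.csv").open() as fh:
        return pd.read_csv(fh)
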