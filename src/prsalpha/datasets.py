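"""Packaged reference tables.

Two small CSVs ship with the package:

* an age-band breast-cancer incidence table emulating the magnitude of the
  England & Wales 2016-2018 female rates (used as the default population
  constraint for the baseline hazard), and
* the published calibration parameters (means, SDs, log-OR per SD, alpha
  estimates) for the BCAC PRS313 and the alternative breast-cancer PRSs
  evaluated against the BOADICEA polygenic model, used by the
  proportionality-calibration routines and their checks.
"""

from importlib import resources

import pandas as pd

from .core_model import IncidenceTable

__all__ = ["load_incidence", "load_published_prs_parameters", "CHEK2_LINKED_VARIANTS"]

#: GRCh37 keys of the two chromosome-22 PRS variants correlated with the
#: CHEK2*1100delC protein-truncating variant; excluded when a PRS is combined
#: with gene-panel testing.
CHEK2_LINKED_VARIANTS = ("22_29203724_C_T", "22_29551872_A_G")


def _data_path(name: str):
    return resources.files("prsalpha").joinpath("data", name)


def load_incidence() -> IncidenceTable:
    """Yearly incidence table expanded from the packaged age-band fixture."""
    with resources.as_file(_data_path("incidence_ew_like.csv")) as p:
        return IncidenceTable.from_csv(p)


def load_published_prs_parameters() -> pd.DataFrame:
    """Published summary parameters for PRS313 and alternative PRSs, indexed by PRS name."""
    with resources.as_file(_data_path("published_prs_parameters.csv")) as p:
        return pd.read_csv(p, index_col="prs")
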