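"""Packaged reference data.

The package ships one small data set: the published before/after-transition
deviation panel from a longitudinal whole-blood methylome study of
ultra-high-risk individuals, covering the 25 candidate CpGs that passed the
variance-scan filters in the 14 subjects who converted to psychosis.  Each
cell is the deviation of an individual's beta-value from the converter-group
median at that CpG and timepoint, printed at 2-decimal precision.  It is the
worked example for the epimutation caller: applying the strict |deviation|
> 0.10 rule to the after-transition block reproduces the study's counts
(12 called CpGs, 16 calls).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import DeviationMatrix

#: printed precision of the panel; comparisons against it use this tolerance
PANEL_DECIMALS = 2


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("methvar.data") / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                           na_values=[""])


def load_epimutation_panel() -> tuple[DeviationMatrix, DeviationMatrix, pd.DataFrame]:
    """Load the 25-CpG x 14-converter deviation panel.

    Returns ``(before, after, candidates)``: deviation matrices at the
    baseline-analog and follow-up-analog timepoints, and the candidate-probe
    annotation (index probe_id; columns gene, q_fdr) whose ``gene`` column
    is the UCSC symbol (empty for intergenic CpGs) and ``q_fdr`` the
    published FDR-adjusted variance-test p-value.
    """
    before = DeviationMatrix(_read("deviation_panel_before.tsv").astype(float),
                             timepoint="M0", group="converter",
                             median_tol=0.5 * 10.0 ** -PANEL_DECIMALS)
    after = DeviationMatrix(_read("deviation_panel_after.tsv").astype(float),
                            timepoint="MF", group="converter",
                            median_tol=0.5 * 10.0 ** -PANEL_DECIMALS)
    candidates = _read("candidate_probes.tsv")
    candidates["gene"] = candidates["gene"].fillna("")
    candidates["q_fdr"] = candidates["q_fdr"].astype(float)
    return before, after, candidates
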