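"""Model/Results interface for the flank-conservation analysis.

``FlankConservation`` bundles the full selection analysis around a
transcription-factor binding site: sliding-window Shannon-entropy
profiles of the 5' and 3' flanks for the with-site and without-site
species groups, a fourfold-degenerate-site resampling null built from a
CDS alignment, and two-sided Mann-Whitney U tests among the three
samples.  ``fit`` returns a ``FlankConservationResults`` object carrying
the profiles, the null ensemble, the tests and a ``summary()`` table.

Two window layouts coexist deliberately: overlapping windows (step 1)
for the descriptive conservation profile, and tiled windows
(step = width) for the group tests, because overlapping window means
share columns and are therefore autocorrelated — treating them as
independent observations would invalidate the rank test.  Both steps
are configurable and echoed into the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .entropy import (
    EntropyProfile,
    FLANKS,
    logo_matrix,
    LogoMatrix,
    pooled_window_values,
    window_scan,
)
from .fourfold import FourfoldSiteIndex, extract_fourfold_sites
from .motifs import (
    CONSENSUS,
    OrthologousWindowSet,
    SequenceRecord,
    WITH_SITE,
    WITHOUT_SITE,
    extract_windows,
)
from .nulls import NullEnsemble, build_null
from .stats import TestResult, compare_groups


class FlankConservation:
    """Conservation comparison of binding-site flanks between species groups.

    Parameters
    ----------
    with_windows, without_windows
        Motif-centred aligned window sets for the two groups, with a
        flank wide enough for the requested window width (the study
        profiles use 12-bp flanks).
    cds
        Optional gap-free codon alignment of orthologous coding
        sequences; enables the fourfold-degenerate resampling null.
    width
        Scan window width in bp (default 6).
    display_step
        Step of the descriptive sliding profile (default 1, overlapping).
    test_step
        Step of the windows pooled into the test samples; defaults to
        ``width`` (tiled, non-overlapping).
    n_null, null_k
        Null-ensemble replicates (default 1,000) and sites sampled per
        replicate (default 6).
    """

    def __init__(
        self,
        with_windows: OrthologousWindowSet,
        without_windows: OrthologousWindowSet,
        cds: Sequence[SequenceRecord] | None = None,
        fourfold_sites: FourfoldSiteIndex | None = None,
        width: int = 6,
        display_step: int = 1,
        test_step: int | None = None,
        n_null: int = 1000,
        null_k: int = 6,
    ) -> None:
        if with_windows.flank != without_windows.flank:
            raise ValueError("the two groups must share the same flank width")
        self.with_windows = with_windows
        self.without_windows = without_windows
        self.cds = list(cds) if cds is not None else None
        self.fourfold_sites = fourfold_sites
        self.width = width
        self.display_step = display_step
        self.test_step = test_step if test_step is not None else width
        self.n_null = n_null
        self.null_k = null_k

    @classmethod
    def from_panel(
        cls,
        panel: Sequence[SequenceRecord],
        anchor_id: str,
        anchor_start: int,
        consensus: str = CONSENSUS,
        flank_len: int = 12,
        cds: Sequence[SequenceRecord] | None = None,
        **kwargs,
    ) -> "FlankConservation":
        """Build the model from an aligned promoter panel and an anchor hit.

        ``flank_len`` is the flank profiled on each side of the hexamer
        (12 or 18 bp in the study; default 12).
        """
        with_set, without_set = extract_windows(
            panel, anchor_id, anchor_start, consensus=consensus, flank=flank_len
        )
        return cls(with_set, without_set, cds=cds, **kwargs)

    def fit(self, seed: int | None = None) -> "FlankConservationResults":
        """Run the analysis; ``seed`` drives the resampling null only."""
        profiles: dict[tuple[str, str], EntropyProfile] = {}
        test_profiles: dict[tuple[str, str], EntropyProfile] = {}
        for windows in (self.with_windows, self.without_windows):
            for side, prof in window_scan(
                windows, width=self.width, step=self.display_step
            ).items():
                profiles[(windows.group, side)] = prof
            for side, prof in window_scan(
                windows, width=self.width, step=self.test_step
            ).items():
                test_profiles[(windows.group, side)] = prof

        null = None
        if self.cds is not None:
            sites = self.fourfold_sites
            if sites is None:
                sites = extract_fourfold_sites(self.cds)
            null = build_null(
                self.cds, sites=sites, n_replicates=self.n_null,
                k=self.null_k, seed=seed,
            )

        with_test = [p for (g, _), p in test_profiles.items() if g == WITH_SITE]
        without_test = [p for (g, _), p in test_profiles.items() if g == WITHOUT_SITE]
        tests, summary = compare_groups(with_test, without_test, null=null)

        logos = {
            WITH_SITE: logo_matrix(self.with_windows),
            WITHOUT_SITE: logo_matrix(self.without_windows),
        }
        return FlankConservationResults(
            model=self,
            profiles=profiles,
            test_profiles=test_profiles,
            null_=null,
            tests=tests,
            group_summary=summary,
            logos=logos,
            seed=seed,
        )


@dataclass
class FlankConservationResults:
    """Fitted flank-conservation analysis.

    ``profiles`` holds the descriptive sliding profiles keyed by
    (group, flank); ``test_profiles`` the tiled windows the tests were
    run on; ``null_`` the resampling null (None when no CDS alignment
    was supplied); ``tests`` the pairwise Mann-Whitney results.
    """

    model: FlankConservation
    profiles: Mapping[tuple[str, str], EntropyProfile]
    test_profiles: Mapping[tuple[str, str], EntropyProfile]
    null_: NullEnsemble | None
    tests: Mapping[str, TestResult]
    group_summary: pd.DataFrame
    logos: Mapping[str, LogoMatrix]
    seed: int | None = None

    def profile_frame(self, which: str = "display") -> pd.DataFrame:
        source = self.profiles if which == "display" else self.test_profiles
        return pd.concat([p.to_frame() for p in source.values()], ignore_index=True)

    def group_values(self, group: str) -> np.ndarray:
        return pooled_window_values(
            [p for (g, _), p in self.test_profiles.items() if g == group]
        )

    def median_entropy(self, group: str) -> float:
        row = self.group_summary.loc[self.group_summary["sample"] == group]
        if row.empty:
            raise KeyError(f"no sample named {group!r}")
        return float(row["median_entropy"].iloc[0])

    def summary(self) -> str:
        """Plain-text summary of samples, medians and pairwise tests."""
        m = self.model
        lines = [
            "Flank conservation analysis",
            "=" * 64,
            f"groups: with_site n={m.with_windows.n}, "
            f"without_site n={m.without_windows.n}",
            f"flank: {m.with_windows.flank} bp per side; window width "
            f"{m.width} bp; display step {m.display_step}; test step {m.test_step}",
        ]
        if self.null_ is not None:
            lines.append(
                f"null: {self.null_.n_replicates} replicates x "
                f"{self.null_.sites_per_replicate} fourfold sites "
                f"(seed={self.null_.seed})"
            )
        lines.append("-" * 64)
        lines.append(f"{'sample':<14}{'n':>6}{'median H':>12}{'mean H':>12}")
        for row in self.group_summary.itertuples():
            lines.append(
                f"{row.sample:<14}{row.n:>6}{row.median_entropy:>12.4f}"
                f"{row.mean_entropy:>12.4f}"
            )
        lines.append("-" * 64)
        lines.append(
            f"{'comparison':<22}{'U':>10}{'p':>12}  method"
        )
        for name, t in self.tests.items():
            lines.append(
                f"{name:<22}{t.statistic:>10.1f}{t.p_value:>12.4g}  "
                f"{t.method}{' (tie-corrected)' if t.tie_corrected else ''}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_profiles(self, ax=None):
        """Line plot of the descriptive sliding-window profiles."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        styles = {WITH_SITE: "-", WITHOUT_SITE: "--"}
        for (group, side), prof in self.profiles.items():
            offset = 0 if side == FLANKS[0] else prof.window_starts.max() + 2
            ax.plot(
                prof.window_starts + offset,
                prof.values,
                styles[group],
                label=f"{group} / {side}",
            )
        if self.null_ is not None:
            ax.axhline(
                float(np.median(self.null_.values)), color="grey", lw=0.8,
                label="null median",
            )
        ax.set_xlabel("window start (bp within flank)")
        ax.set_ylabel("mean Shannon entropy (bits)")
        ax.legend(fontsize=7)
        return ax
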