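"""ZooMS: collagen peptide mass fingerprinting of MALDI-TOF peak lists.

Taxa are identified by matching observed peaks (900-4000 m/z) against a
panel of collagen tryptic-peptide marker masses.  Taxa sharing all their
observed markers cannot be separated and are reported as an ambiguity
group (e.g. several carnivore families when the discriminating marker A
is absent from the spectrum).  An empty spectrum is reported as
"No Collagen"; a spectrum matching no panel taxon as "unidentified".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

NO_COLLAGEN = "No Collagen"
UNIDENTIFIED = "unidentified"

#: Hominin collagen peptide marker masses (m/z)
HOMININ_MARKERS = {"A": 1235.6, "B": 1477.8, "D": 2115.1, "E": 2832.4, "G": 2957.5}


@dataclass
class PeptideMarkerPanel:
    """Marker masses per taxon plus ambiguity-group labels.

    ``table`` columns: taxon, marker, mz.  ``groups`` maps a frozenset of
    taxa indistinguishable without further markers to the label reported
    for that set (e.g. "Mustelidae/Pantherinae/Hyaenidae").
    """

    table: pd.DataFrame
    groups: dict[frozenset, str] = field(default_factory=dict)

    def __post_init__(self):
        dup = self.table.duplicated(subset=["taxon", "marker"])
        if dup.any():
            raise ValueError("duplicate (taxon, marker) pairs in panel")
        bad = ~self.table["mz"].between(900, 4000, inclusive="neither")
        if bad.any():
            raise ValueError("marker m/z must lie in (900, 4000)")

    @property
    def taxa(self) -> list[str]:
        return sorted(self.table["taxon"].unique())

    def markers_for(self, taxon: str) -> dict[str, float]:
        sub = self.table[self.table["taxon"] == taxon]
        if sub.empty:
            raise KeyError(f"unknown taxon: {taxon!r}")
        return dict(zip(sub["marker"], sub["mz"]))

    def group_label(self, taxa: set[str]) -> str | None:
        return self.groups.get(frozenset(taxa))


@dataclass
class ZoomsCall:
    specimen_id: str
    label: str
    candidates: list[str] = field(default_factory=list)
    matched: dict[str, list[str]] = field(default_factory=dict)
    missing: dict[str, list[str]] = field(default_factory=dict)
    series: str | None = None  # 'complete' | 'partial'


def default_panel() -> PeptideMarkerPanel:
    """The shipped demonstration panel.

    Contains the five hominin marker masses plus synthetic demonstration
    taxa mimicking the ambiguity structure of published marker compendia
    (their masses are invented, labelled synthetic in the data file); real
    analyses should supply the full published panel as user config.
    """
    path = resources.files("paleoproof.data").joinpath("zooms_markers.tsv")
    with resources.as_file(path) as p:
        table = pd.read_csv(p, sep="\t")
    groups = {
        frozenset({"Mustelidae", "Pantherinae", "Hyaenidae"}): "Mustelidae/Pantherinae/Hyaenidae",
        frozenset({"Cervid", "Saiga"}): "Cervid/Saiga",
    }
    return PeptideMarkerPanel(table=table, groups=groups)


def read_peaklist(path, specimen_id: str | None = None) -> pd.DataFrame:
    """Two-column CSV (mz, intensity) -> ascending-m/z DataFrame."""
    df = pd.read_csv(path)
    if not {"mz", "intensity"}.issubset(df.columns):
        raise ValueError("peak list needs 'mz' and 'intensity' columns")
    if (df["intensity"] < 0).any():
        raise ValueError("intensities must be >= 0")
    return df.sort_values("mz", ignore_index=True)


def match_markers(
    peaks: pd.DataFrame,
    panel: PeptideMarkerPanel,
    tolerance: float = 0.2,
    min_intensity: float = 0.0,
) -> pd.DataFrame:
    """Matched/missing markers per taxon.

    A marker matches when any peak lies within +/- ``tolerance`` of its
    m/z; one peak may satisfy several markers.  Intensity is ignored for
    matching apart from the optional ``min_intensity`` floor.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    usable = peaks[peaks["intensity"] >= min_intensity]["mz"].to_numpy()
    rows = []
    for taxon in panel.taxa:
        for marker, mz in sorted(panel.markers_for(taxon).items()):
            hit = bool(len(usable)) and bool((abs(usable - mz) <= tolerance).any())
            rows.append({"taxon": taxon, "marker": marker, "mz": mz, "matched": hit})
    return pd.DataFrame(rows)


def classify(
    match_table: pd.DataFrame,
    panel: PeptideMarkerPanel,
    specimen_id: str = "specimen",
    min_markers: int = 2,
    n_peaks: int | None = None,
    min_peak_count: int = 1,
) -> ZoomsCall:
    """Taxonomic call from a marker match table.

    Candidates are taxa with at least ``min_markers`` matched markers and
    no conflicting discriminating marker: a marker letter whose
    taxon-specific mass is absent from the spectrum while another
    candidate's mass for the same letter is present argues against the
    taxon.  Indistinguishable candidate sets are reported under the
    panel's group label.  ``n_peaks`` below ``min_peak_count`` (e.g. an
    empty spectrum) yields "No Collagen".
    """
    if n_peaks is not None and n_peaks < min_peak_count:
        return ZoomsCall(specimen_id, NO_COLLAGEN)
    matched = {
        t: sorted(g[g["matched"]]["marker"])
        for t, g in match_table.groupby("taxon")
    }
    missing = {
        t: sorted(g[~g["matched"]]["marker"])
        for t, g in match_table.groupby("taxon")
    }
    candidates = []
    for taxon, hits in matched.items():
        if len(hits) < min_markers:
            continue
        # conflict: for some marker letter this taxon misses its mass while
        # a different taxon's mass for the same letter is in the spectrum
        conflict = False
        for letter in missing[taxon]:
            others = match_table[
                (match_table["marker"] == letter)
                & (match_table["taxon"] != taxon)
                & match_table["matched"]
            ]
            if not others.empty:
                other_masses = set(others["mz"])
                own = match_table[
                    (match_table["marker"] == letter) & (match_table["taxon"] == taxon)
                ]["mz"]
                if not own.empty and set(own) != other_masses:
                    conflict = True
                    break
        if not conflict:
            candidates.append(taxon)
    if not candidates:
        return ZoomsCall(specimen_id, UNIDENTIFIED, matched=matched, missing=missing)
    if len(candidates) == 1:
        taxon = candidates[0]
        series = "complete" if not missing[taxon] else "partial"
        return ZoomsCall(
            specimen_id, taxon, [taxon], matched, missing, series=series
        )
    # several indistinguishable candidates -> ambiguity-group label
    best = max(len(matched[t]) for t in candidates)
    top = {t for t in candidates if len(matched[t]) == best}
    label = panel.group_label(top)
    if label is None:
        label = "/".join(sorted(top))
    series = "complete" if all(not missing[t] for t in top) else "partial"
    return ZoomsCall(
        specimen_id, label, sorted(top), matched, missing, series=series
    )


def classify_peaklist(
    peaks: pd.DataFrame,
    panel: PeptideMarkerPanel | None = None,
    specimen_id: str = "specimen",
    tolerance: float = 0.2,
    min_markers: int = 2,
) -> ZoomsCall:
    """Convenience wrapper: peak list -> taxonomic call."""
    panel = panel or default_panel()
    table = match_markers(peaks, panel, tolerance=tolerance)
    return classify(
        table, panel, specimen_id=specimen_id, min_markers=min_markers, n_peaks=len(peaks)
    )
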