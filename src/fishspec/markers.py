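"""Band-level marker statistics: peak intensities at named wavenumbers,
ratios against the amide III 1186 cm^-1 band, one-way ANOVA + Tukey HSD
group comparisons, and spectra-to-physicochemistry correlation via a seeded
random tripartition of the spectra.

The packaged band table (``load_band_table``) lists the 14 marker
wavenumbers in the 900–1780 cm^-1 fingerprint region with their molecular
assignments and whether each marks fresh (D0) or aged (D7) tissue.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .spectra import SpectraSet

__all__ = [
    "load_band_table",
    "peak_intensity",
    "band_ratios",
    "group_compare",
    "correlate_physchem",
]


def load_band_table() -> pd.DataFrame:
    """Packaged marker-band inventory (wavenumber, biomarker_for, assignment)."""
    with resources.files("fishspec.data").joinpath("band_assignments.csv").open() as fh:
        return pd.read_csv(fh)


def peak_intensity(spectra_set: SpectraSet, wavenumber: float, window: float = 5.0,
                   mode: str = "max") -> pd.DataFrame:
    """Per-spectrum intensity at (or near) a nominal wavenumber.

    ``mode="max"``: maximum within the closed window ``wavenumber ± window``
    and its location. ``mode="interp"``: linear interpolation exactly at the
    nominal wavenumber.

    Returns a DataFrame with columns ``spectrum_id, day, wavenumber_nominal,
    wavenumber_found, intensity, window_halfwidth``.
    """
    g = spectra_set.grid
    if wavenumber + window < g[0] or wavenumber - window > g[-1]:
        raise ValueError(
            f"window {wavenumber}±{window} cm^-1 outside grid [{g[0]}, {g[-1]}]"
        )
    if mode == "max":
        mask = (g >= wavenumber - window) & (g <= wavenumber + window)
        sub = spectra_set.intensities[:, mask]
        j = np.argmax(sub, axis=1)
        found = g[mask][j]
        inten = sub[np.arange(sub.shape[0]), j]
    elif mode == "interp":
        inten = np.array([np.interp(wavenumber, g, row) for row in spectra_set.intensities])
        found = np.full(len(spectra_set), float(wavenumber))
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'max' or 'interp'")
    return pd.DataFrame({
        "spectrum_id": spectra_set.meta["spectrum_id"],
        "day": spectra_set.meta["day"],
        "wavenumber_nominal": float(wavenumber),
        "wavenumber_found": found,
        "intensity": inten,
        "window_halfwidth": float(window),
    })


def band_ratios(spectra_set: SpectraSet, bands: pd.DataFrame | None = None,
                denominator: float = 1186.0, window: float = 5.0) -> pd.DataFrame:
    """Per-spectrum band intensities normalised against a denominator band.

    Ratios are invariant to any global multiplicative rescaling of a
    spectrum, so they transfer across instruments and section thicknesses.
    A non-positive denominator intensity yields NaN ratios and
    ``denominator_ok=False`` for that spectrum rather than a global failure.
    """
    if bands is None:
        bands = load_band_table()
    denom = peak_intensity(spectra_set, denominator, window)["intensity"].to_numpy()
    ok = denom > 0
    out = spectra_set.meta[["spectrum_id", "day"]].copy()
    out["denominator_ok"] = ok
    safe = np.where(ok, denom, np.nan)
    for w in bands["wavenumber"]:
        if float(w) == float(denominator):
            continue
        num = peak_intensity(spectra_set, float(w), window)["intensity"].to_numpy()
        out[f"r{w:g}"] = num / safe
    return out


def _compact_letters(groups, sig_pairs) -> dict:
    """Compact letter display: groups sharing a letter are not significantly
    different (insert-absorb algorithm)."""
    cliques = [set(groups)]
    for a, b in sig_pairs:
        new = []
        for c in cliques:
            if a in c and b in c:
                new.extend([c - {b}, c - {a}])
            else:
                new.append(c)
        # absorb sets contained in another
        cliques = [c for c in new
                   if c and not any(c < d or (c == d and new.index(d) < new.index(c))
                                    for d in new)]
    letters = {g: set() for g in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, c in enumerate(sorted(cliques, key=lambda c: sorted(groups.index(g) for g in c))):
        for g in c:
            letters[g].add(alphabet[i % len(alphabet)])
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def group_compare(values, labels, alpha: float = 0.05) -> dict:
    """One-way ANOVA across day groups with Tukey HSD post hoc tests.

    Returns ``{"F", "p", "tukey": DataFrame, "letters": {day: letters}}``.
    Groups whose letters share a character are not distinguishable at
    ``alpha``. Fully degenerate input (zero variance everywhere) is reported
    as F=0, p=1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [g for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    by_group = [values[labels == g] for g in groups]
    if any(len(v) < 2 for v in by_group):
        small = [g for g, v in zip(groups, by_group) if len(v) < 2]
        raise ValueError(f"group(s) {small} have fewer than 2 values")

    if np.allclose(values, values[0]):
        # no variance at all: nothing to test
        tukey = pd.DataFrame(columns=["group1", "group2", "meandiff", "p-adj",
                                      "lower", "upper", "reject"])
        return {"F": 0.0, "p": 1.0, "tukey": tukey,
                "letters": {g: "a" for g in groups}}

    F, p = stats.f_oneway(*by_group)
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    sig = [(row["group1"], row["group2"]) for _, row in tukey.iterrows() if row["reject"]]
    letters = _compact_letters(list(groups), sig)
    return {"F": float(F), "p": float(p), "tukey": tukey, "letters": letters}


def tripartition(spectra_set: SpectraSet, seed: int = 0) -> np.ndarray:
    """Seeded random split of each fish/day cell into 3 near-equal blocks.

    Returns a block index (1..3) per spectrum; within every fish/day the
    blocks are disjoint and cover all spectra.
    """
    rng = np.random.default_rng(seed)
    block = np.zeros(len(spectra_set), dtype=int)
    for _, idx in spectra_set.meta.groupby(["fish_id", "day"]).groups.items():
        idx = np.asarray(idx)
        perm = rng.permutation(idx.size)
        block[idx] = perm % 3 + 1
    return block


def correlate_physchem(spectra_set: SpectraSet, bands: pd.DataFrame | None,
                       physchem: pd.DataFrame, seed: int = 0,
                       window: float = 5.0) -> pd.DataFrame:
    """Pearson correlation of block-mean band intensities with
    physicochemical replicates.

    Each fish/day cell's spectra are randomly (but reproducibly) divided
    into 3 blocks whose mean peak intensities are paired with that cell's 3
    physicochemical replicates; r and p are computed per band x variable
    across all pairs.
    """
    if bands is None:
        bands = load_band_table()
    pc_keys = set(map(tuple, physchem[["fish_id", "day"]].drop_duplicates().itertuples(index=False)))
    sp_keys = set(map(tuple, spectra_set.meta[["fish_id", "day"]].drop_duplicates().itertuples(index=False)))
    if pc_keys != sp_keys:
        raise ValueError(
            "fish/day mismatch between spectra and physicochemical table; "
            f"only in spectra: {sorted(sp_keys - pc_keys)}; "
            f"only in physchem: {sorted(pc_keys - sp_keys)}"
        )
    block = tripartition(spectra_set, seed)
    variables = [c for c in physchem.columns if c not in ("fish_id", "day", "replicate")]

    # block-mean intensity per band per (fish, day, block)
    frames = {}
    for w in bands["wavenumber"]:
        pk = peak_intensity(spectra_set, float(w), window)
        pk["fish_id"] = spectra_set.meta["fish_id"].to_numpy()
        pk["block"] = block
        frames[float(w)] = pk.groupby(["fish_id", "day", "block"])["intensity"].mean()

    pc = physchem.set_index(["fish_id", "day", "replicate"]).sort_index()
    rows = []
    for w, means in frames.items():
        aligned = means.rename_axis(["fish_id", "day", "replicate"])
        joined = pd.concat([aligned.rename("intensity"), pc], axis=1, join="inner")
        for var in variables:
            r, p = stats.pearsonr(joined["intensity"], joined[var])
            rows.append({"wavenumber": w, "variable": var, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
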