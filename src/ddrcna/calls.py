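"""Probe-level copy-number states -> filtered CNA regions -> gene-level calls.

The pipeline mirrors standard aCGH post-processing: runs of probes sharing a
non-neutral state are collapsed into contiguous regions, regions supported by
a single probe are dropped, regions inside assembly gaps (centromeres /
telomeres) are removed and regions straddling a gap are trimmed
conservatively (shortened, never elongated), and the surviving regions are
intersected with a merged gene annotation to produce per-patient gene calls
in {loss, neutral, gain}.

Conventions
-----------
* Coordinates are 0-based half-open; a region spans
  ``[first probe position, last probe position + 1)`` because probe target
  extents are unknown — the conservative point reading.
* States are encoded as int8: loss=-1, neutral=0, gain=+1
  (:data:`STATE_CODES`).
* Probes are assumed to lie on a shared per-chromosome grid (one platform),
  so trimmed regions can be re-snapped to probe positions and supporting
  probes recounted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

STATE_CODES = {"loss": -1, "neutral": 0, "gain": 1}
CODE_STATES = {v: k for k, v in STATE_CODES.items()}

REGION_COLUMNS = ["patient_id", "chrom", "start", "end", "state", "n_probes"]


def _state_to_code(state: pd.Series) -> np.ndarray:
    if pd.api.types.is_integer_dtype(state):
        codes = state.to_numpy()
        bad = ~np.isin(codes, (-1, 0, 1))
    else:
        codes = state.map(STATE_CODES).to_numpy(dtype=float)
        bad = np.isnan(codes)
    if bad.any():
        raise DataError(
            f"invalid probe state(s): {sorted(state[bad].astype(str).unique())}"
        )
    return codes.astype(np.int8)


def collapse_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-probe states into contiguous same-state aberrant regions.

    Parameters
    ----------
    probes : DataFrame with columns patient_id, chrom, pos, state
        ``state`` may be the string alphabet {loss, neutral, gain} or the
        int codes {-1, 0, 1}.  Rows need not be sorted.

    Returns
    -------
    DataFrame with columns patient_id, chrom, start, end, state, n_probes —
    one row per maximal run of identical non-neutral state within one
    patient's chromosome, sorted by (patient, chrom, start).  Neutral runs
    emit nothing; runs never cross chromosome boundaries.

    Raises
    ------
    DataError
        If a (patient, chrom, pos) occurs twice with conflicting states.
    """
    required = {"patient_id", "chrom", "pos", "state"}
    if not required.issubset(probes.columns):
        raise DataError(f"probe table must have columns {sorted(required)}")
    if len(probes) == 0:
        return pd.DataFrame(columns=REGION_COLUMNS)

    df = probes[["patient_id", "chrom", "pos"]].copy()
    df["code"] = _state_to_code(probes["state"])
    df = df.sort_values(["patient_id", "chrom", "pos"], kind="stable")

    pid = df["patient_id"].to_numpy()
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    code = df["code"].to_numpy()

    same_track = (pid[1:] == pid[:-1]) & (chrom[1:] == chrom[:-1])
    dup = same_track & (pos[1:] == pos[:-1])
    if dup.any():
        i = int(np.flatnonzero(dup)[0]) + 1
        if code[i] != code[i - 1]:
            raise DataError(
                f"conflicting duplicate probe at {chrom[i]}:{pos[i]} "
                f"for patient {pid[i]}"
            )
        raise DataError(
            f"duplicate probe position {chrom[i]}:{pos[i]} for patient {pid[i]}"
        )

    # run-length encode over the whole sorted table at once
    new_run = np.empty(len(df), dtype=bool)
    new_run[0] = True
    new_run[1:] = ~same_track | (code[1:] != code[:-1])
    run_start = np.flatnonzero(new_run)
    run_end = np.r_[run_start[1:], len(df)]  # exclusive row index

    keep = code[run_start] != 0
    rs, re = run_start[keep], run_end[keep]
    out = pd.DataFrame(
        {
            "patient_id": pid[rs],
            "chrom": chrom[rs],
            "start": pos[rs].astype(np.int64),
            "end": pos[re - 1].astype(np.int64) + 1,
            "state": code[rs],
            "n_probes": (re - rs).astype(np.int64),
        }
    )
    return out.reset_index(drop=True)


def _snap(start, end, grid):
    """Snap interval [start, end) to the probe grid; return (s, e, n) or None."""
    i = np.searchsorted(grid, start, side="left")
    j = np.searchsorted(grid, end, side="left")  # grid[j-1] < end
    if j <= i:
        return None
    return int(grid[i]), int(grid[j - 1]) + 1, int(j - i)


def filter_regions(
    regions: pd.DataFrame,
    gaps: pd.DataFrame,
    probe_positions: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Apply the single-probe filter and conservative gap trimming.

    Order of operations: (1) drop regions with a single supporting probe;
    (2) for every assembly gap, drop regions wholly inside it and shorten
    regions partially overlapping it (a region bisected by a gap yields two
    flanks, each re-snapped to the probe grid with its probe count
    recomputed); (3) re-apply the single-probe filter to the flanks.

    Parameters
    ----------
    regions : output of :func:`collapse_probes`
    gaps : DataFrame with columns chrom, start, end (kind ignored)
    probe_positions : mapping chrom -> sorted array of probe positions,
        used to recount supporting probes after trimming.

    Raises
    ------
    DataError
        If a region lies on a chromosome absent from ``probe_positions``.
    """
    if len(regions) == 0:
        return regions.reindex(columns=REGION_COLUMNS)

    unknown = set(regions["chrom"].unique()) - set(probe_positions)
    if unknown:
        raise DataError(f"regions on chromosome(s) without probe grid: {sorted(unknown)}")

    work = regions[regions["n_probes"] >= 2].copy()

    gap_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, gs, ge in gaps[["chrom", "start", "end"]].itertuples(index=False):
        gap_by_chrom.setdefault(chrom, []).append((int(gs), int(ge)))

    pieces = []
    for chrom, sub in work.groupby("chrom", sort=False, observed=True):
        grid = np.asarray(probe_positions[chrom])
        start = sub["start"].to_numpy(np.int64)
        end = sub["end"].to_numpy(np.int64)
        n = sub["n_probes"].to_numpy(np.int64)
        pid = sub["patient_id"].to_numpy()
        state = sub["state"].to_numpy()
        for gs, ge in sorted(gap_by_chrom.get(chrom, [])):
            hits = (start < ge) & (end > gs)
            if not hits.any():
                continue
            keep_start = [start[~hits]]
            keep_end = [end[~hits]]
            keep_n = [n[~hits]]
            keep_pid = [pid[~hits]]
            keep_state = [state[~hits]]
            for s, e, st, p in zip(start[hits], end[hits], state[hits], pid[hits]):
                for fs, fe in ((s, min(e, gs)), (max(s, ge), e)):
                    snapped = None if fe <= fs else _snap(fs, fe, grid)
                    if snapped is None:
                        continue
                    keep_start.append(np.array([snapped[0]]))
                    keep_end.append(np.array([snapped[1]]))
                    keep_n.append(np.array([snapped[2]]))
                    keep_pid.append(np.array([p], dtype=pid.dtype))
                    keep_state.append(np.array([st], dtype=state.dtype))
            start = np.concatenate(keep_start)
            end = np.concatenate(keep_end)
            n = np.concatenate(keep_n)
            pid = np.concatenate(keep_pid)
            state = np.concatenate(keep_state)
        pieces.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "state": state,
                    "n_probes": n,
                }
            )
        )

    out = pd.concat(pieces, ignore_index=True) if pieces else work
    out = out[out["n_probes"] >= 2]
    return out.sort_values(
        ["patient_id", "chrom", "start"], kind="stable", ignore_index=True
    )


def intersect_genes(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    patients=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project filtered CNA regions onto a merged gene annotation.

    A gene is called gain (loss) when at least 1 bp of a gain (loss) region
    overlaps it.  When both states overlap a gene the state with the larger
    total overlap wins; an exact tie yields neutral with a logged warning.

    Parameters
    ----------
    regions : filtered region table
    genes : DataFrame with columns chrom, start, end, symbol (merged:
        non-overlapping per chromosome)
    patients : optional iterable of patient ids fixing the row universe;
        defaults to the patients present in ``regions``.  Patients without
        regions get an all-neutral row.

    Returns
    -------
    (matrix, provenance)
        ``matrix`` — DataFrame patients x gene symbols with int8 entries in
        {-1, 0, 1}; ``provenance`` — long DataFrame (patient_id, symbol,
        state, overlap_bp) with one row per non-neutral call.
    """
    if patients is None:
        patients = pd.unique(regions["patient_id"])
    patients = pd.Index(patients, name="patient_id")
    symbols = list(genes["symbol"])
    matrix = pd.DataFrame(
        np.zeros((len(patients), len(symbols)), dtype=np.int8),
        index=patients,
        columns=symbols,
    )
    prov_rows = []
    if len(regions):
        pid_codes, pid_uniques = pd.factorize(regions["patient_id"])
        pidx = patients.get_indexer(pid_uniques)
        if (pidx < 0).any():
            stray = list(pd.Index(pid_uniques)[pidx < 0][:5])
            raise DataError(f"regions reference patients outside the cohort: {stray}")
        rstart = regions["start"].to_numpy(np.int64)
        rend = regions["end"].to_numpy(np.int64)
        rstate = regions["state"].to_numpy()
        rchrom = regions["chrom"].to_numpy()
        for chrom, gstart, gend, symbol in genes[
            ["chrom", "start", "end", "symbol"]
        ].itertuples(index=False):
            on = rchrom == chrom
            ov = np.minimum(rend[on], gend) - np.maximum(rstart[on], gstart)
            ov = np.clip(ov, 0, None)
            hit = ov > 0
            if not hit.any():
                continue
            rows = pidx[pid_codes[on][hit]]
            gain_bp = np.zeros(len(patients), dtype=np.int64)
            loss_bp = np.zeros(len(patients), dtype=np.int64)
            st = rstate[on][hit]
            np.add.at(gain_bp, rows[st == 1], ov[hit][st == 1])
            np.add.at(loss_bp, rows[st == -1], ov[hit][st == -1])
            call = np.sign(gain_bp - loss_bp).astype(np.int8)
            tied = (gain_bp == loss_bp) & (gain_bp > 0)
            if tied.any():
                for p in patients[tied]:
                    logger.warning(
                        "gene %s: equal gain/loss overlap for patient %s -> neutral",
                        symbol,
                        p,
                    )
            matrix[symbol] = call
            for r in np.flatnonzero(call != 0):
                bp = gain_bp[r] if call[r] == 1 else loss_bp[r]
                prov_rows.append((patients[r], symbol, int(call[r]), int(bp)))
    provenance = pd.DataFrame(
        prov_rows, columns=["patient_id", "symbol", "state", "overlap_bp"]
    )
    return matrix, provenance


def gene_frequency_report(
    matrix: pd.DataFrame, genes_of_interest=None
) -> pd.DataFrame:
    """Per-gene counts and percentages of gains, losses and any alteration.

    Percentages are 100 x altered patients / total patients.  An empty
    ``genes_of_interest`` reports over every column of the matrix.
    """
    if len(matrix) == 0:
        raise DataError("empty gene CNA matrix")
    if not genes_of_interest:
        genes_of_interest = list(matrix.columns)
    unknown = [g for g in genes_of_interest if g not in matrix.columns]
    if unknown:
        raise DataError(
            f"unknown gene symbol(s) {unknown}; valid: {list(matrix.columns)}"
        )
    n = len(matrix)
    rows = []
    for g in genes_of_interest:
        col = matrix[g]
        gains = int((col == 1).sum())
        losses = int((col == -1).sum())
        rows.append(
            {
                "symbol": g,
                "n_patients": n,
                "n_gain": gains,
                "n_loss": losses,
                "n_any": gains + losses,
                "pct_gain": 100.0 * gains / n,
                "pct_loss": 100.0 * losses / n,
                "pct_any": 100.0 * (gains + losses) / n,
            }
        )
    return pd.DataFrame(rows)
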