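"""Single-command workflow execution with run manifests.

``run_workflow`` dispatches a validated :class:`RunConfig` to the named
workflow over all input files, optionally in parallel with per-file
isolation (outputs are independent of the worker count), and writes a
manifest recording the config snapshot, package version, file list and
per-file result counts.  Per-file failures are logged and skipped; the
exit status is nonzero only when every file fails.
"""

from __future__ import annotations

import glob
import json
import logging
import os
from concurrent.futures import ProcessPoolExecutor
from typing import Optional

import pandas as pd

from . import __version__
from .aggregate import aggregate_variants, consensus_from_aligned
from .config import RunConfig
from .ddia import extract_dda, extract_dia
from .deconv import clusters_to_spectra, deconvolute_file, link_true_positive
from .errors import CsakitError, InputError
from .fsa import search as fsa_search
from .fsa import summarize_study
from .ms1 import read_aligned_table, read_peaklist, read_scans
from .spectra_io import build_fsdb, load_fsdb, read_spectra, save_fsdb, write_msp

__all__ = ["run_workflow"]

logger = logging.getLogger(__name__)


def _expand(paths) -> list[str]:
    if paths is None:
        return []
    if isinstance(paths, str):
        paths = [paths]
    out: list[str] = []
    for p in paths:
        matches = sorted(glob.glob(p))
        out.extend(matches if matches else [p])
    return out


def _stem(path: str) -> str:
    return os.path.splitext(os.path.basename(path))[0]


def _pair_inputs(config: RunConfig) -> list[tuple[str, str]]:
    """Pair scan files with peak lists by filename stem (fallback: order)."""
    scan_files = _expand(config.io.get("scans"))
    peak_files = _expand(config.io.get("peaklists"))
    if not scan_files or not peak_files:
        raise InputError("workflow requires io.scans and io.peaklists")
    by_stem = {_stem(p): p for p in peak_files}
    pairs = []
    for scan_path in scan_files:
        peak_path = by_stem.get(_stem(scan_path))
        if peak_path is None:
            if len(peak_files) == len(scan_files):
                peak_path = peak_files[scan_files.index(scan_path)]
            else:
                raise InputError(f"no peak list matches scans file {scan_path}")
        pairs.append((scan_path, peak_path))
    return pairs


def _process_file(args) -> tuple[str, Optional[str], int, Optional[str]]:
    """One (scan, peaklist) unit; returns (file_id, out_path, count, error)."""
    workflow, scan_path, peak_path, aligned_path, out_dir, config = args
    file_id = _stem(scan_path)
    try:
        scans = read_scans(scan_path)
        peaks = read_peaklist(peak_path)
        aligned = read_aligned_table(aligned_path) if aligned_path else None
        if workflow == "csa":
            clusters = deconvolute_file(scans, peaks, params=config.csa,
                                        aligned=aligned, file_id=file_id)
            targets_path = config.io.get("targets")
            if targets_path:
                targets = pd.read_csv(targets_path, sep="\t").to_dict("records")
                link_true_positive(clusters, targets)
            spectra = clusters_to_spectra(clusters)
        elif workflow == "dda":
            spectra = extract_dda(scans, peaks, params=config.dda)
        elif workflow == "dia":
            spectra = extract_dia(scans, peaks, params=config.dia)
        else:
            raise InputError(f"unsupported per-file workflow: {workflow}")
        out_path = os.path.join(out_dir, f"{file_id}_{workflow.upper()}.msp")
        if spectra:
            write_msp(spectra, out_path)
        else:
            out_path = None
        return (file_id, out_path, len(spectra), None)
    except (CsakitError, OSError, ValueError) as exc:
        logger.error("file %s failed: %s", file_id, exc)
        return (file_id, None, 0, str(exc))


def run_workflow(config: RunConfig) -> tuple[int, dict]:
    """Execute the configured workflow; returns (exit_status, manifest)."""
    config.validate()
    out_dir = config.io.get("output_dir", ".")
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {
        "config": config.snapshot(),
        "version": __version__,
        "files": [],
        "counts": {},
    }
    status = 0

    if config.workflow in ("csa", "dda", "dia"):
        pairs = _pair_inputs(config)
        aligned_path = config.io.get("aligned")
        jobs = [
            (config.workflow, sp, pp, aligned_path, out_dir, config) for sp, pp in pairs
        ]
        if config.threads > 1 and len(jobs) > 1:
            with ProcessPoolExecutor(max_workers=config.threads) as pool:
                results = list(pool.map(_process_file, jobs))
        else:
            results = [_process_file(job) for job in jobs]
        failures = 0
        for file_id, out_path, count, error in results:
            manifest["files"].append(
                {"file": file_id, "output": out_path, "count": count, "error": error})
            manifest["counts"][file_id] = count
            if error is not None:
                failures += 1
        if failures == len(results) and results:
            status = 1

    elif config.workflow == "aggregate":
        msp_files = _expand(config.io.get("queries"))
        if not msp_files:
            raise InputError("aggregate workflow requires io.queries (MSP files)")
        stream = []
        for path in msp_files:
            for i, spec in enumerate(read_spectra(path)):
                stream.append((_stem(path), str(i), spec))
        agg = config.aggregate
        variants = aggregate_variants(stream, rt_window=agg.rt_window,
                                      entsim_min=agg.entsim_min,
                                      fragment_mz_tol=agg.fragment_mz_tol)
        reps = []
        rows = []
        for vi, variant in enumerate(variants):
            rep = variant.representative.replace()
            rep.metadata["Variant_id"] = str(vi)
            rep.metadata["Detection_frequency"] = str(variant.detection_frequency)
            rep.metadata["Members"] = ";".join(f"{f}:{s}" for f, s in variant.member_refs)
            reps.append(rep)
            rows.append({"variant_id": vi, "rt_center": variant.rt_center,
                         "n_members": variant.n_members,
                         "detection_frequency": variant.detection_frequency})
        write_msp(reps, os.path.join(out_dir, "variants.msp"))
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "variant_frequencies.tsv"),
                                  sep="\t", index=False)
        manifest["counts"]["variants"] = len(variants)

    elif config.workflow == "build-db":
        library = _expand(config.io.get("library"))
        if not library:
            raise InputError("build-db workflow requires io.library")
        spectra = []
        for path in library:
            spectra.extend(read_spectra(path))
        fsdb = build_fsdb(spectra, params=config.search)
        out_path = config.io.get("fsdb", os.path.join(out_dir, "library.fsdb.json"))
        save_fsdb(fsdb, out_path)
        manifest["counts"]["entries"] = len(fsdb)

    elif config.workflow == "search":
        fsdb_path = config.io.get("fsdb")
        if not fsdb_path:
            raise InputError("search workflow requires io.fsdb")
        fsdb = load_fsdb(fsdb_path)
        query_files = _expand(config.io.get("queries"))
        if not query_files:
            raise InputError("search workflow requires io.queries")
        for path in query_files:
            rows = []
            for qi, query in enumerate(read_spectra(path)):
                for hit in fsa_search(query, fsdb, params=config.search):
                    rows.append({
                        "query_id": qi, "query_name": query.name,
                        "library_entry": hit.library_entry_id, "compound": hit.name,
                        "rank": hit.rank, "score": hit.score, "cosine": hit.cosine,
                        "entropy_similarity": hit.entropy_sim, "neme": hit.neme,
                        "np": hit.np_matched,
                    })
            out_path = os.path.join(out_dir, f"{_stem(path)}_hits.tsv")
            pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)
            manifest["counts"][_stem(path)] = len(rows)

    elif config.workflow == "summarize":
        hit_files = _expand(config.io.get("queries"))
        if not hit_files:
            raise InputError("summarize workflow requires io.queries (hit tables)")
        aligned = (read_aligned_table(config.io["aligned"])
                   if config.io.get("aligned") else None)
        per_sample = {}
        for path in hit_files:
            table = pd.read_csv(path, sep="\t")
            if "row_id" not in table.columns and "query_id" in table.columns:
                table = table.rename(columns={"query_id": "row_id"})
            per_sample[_stem(path)] = table
        summary = summarize_study(per_sample, aligned)
        summary.to_csv(os.path.join(out_dir, "study_summary.tsv"), sep="\t", index=False)
        manifest["counts"]["annotations"] = len(summary)

    else:
        raise InputError(f"workflow {config.workflow!r} is not runnable here")

    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return status, manifest
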