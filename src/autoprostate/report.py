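"""Structured case report: four sections rendered to JSON and static HTML.

The report mirrors the clinical template: *Patient Details*, *Prostate
Size and PSA Density*, *Clinically Significant Lesion Candidates* (sorted
descending by probability, labeled LESION 1..N), and a *Findings Summary*
paragraph populated from the other sections. JSON is the canonical
machine-readable artifact (sorted keys, fixed rounding, byte-stable);
HTML is a self-contained static page with optional per-lesion overlay
images of the segmentation contour on the T2 slice.

Rounding: lengths and volumes 1 dp, PSA density 3 dp, probabilities whole
percent — applied once at build time so JSON and HTML always agree.
"""

from __future__ import annotations

import hashlib
import html as _html
import json
from dataclasses import dataclass
from pathlib import Path

from . import __version__ as _pkg_version
from .core_io import PatientRecord
from .measurements import LesionCandidate, ProstateMeasurements, rank_lesions

__all__ = ["ReportDocument", "build_report", "render_json", "render_html"]

SECTION_TITLES = (
    "Patient Details",
    "Prostate Size and PSA Density",
    "Clinically Significant Lesion Candidates",
    "Findings Summary",
)


@dataclass(frozen=True)
class ReportDocument:
    patient: dict
    prostate: dict
    lesions: list  # ordered, descending probability
    findings_summary: str
    provenance: dict


def _fmt_date(d) -> str | None:
    return None if d is None else d.isoformat()


def build_report(
    patient: PatientRecord,
    measurements: ProstateMeasurements,
    lesions: list[LesionCandidate],
    config_hash: str = "",
) -> ReportDocument:
    """Assemble the deterministic report document."""
    ordered = rank_lesions(list(lesions))
    lesion_rows = []
    for i, les in enumerate(ordered, start=1):
        lesion_rows.append(
            {
                "label": f"LESION {i}",
                "probability_pct": round(100.0 * les.probability),
                "volume_cm3": round(les.volume_cm3, 1),
                "centroid_slice": les.centroid_slice,
                "centroid_zone": les.centroid_zone,
                "centroid_region": les.centroid_region,
                "min_adc_mm2_s": les.min_adc,
                "extracapsular": les.extracapsular,
            }
        )

    psad = measurements.psa_density
    prostate = {
        "transverse_cm": round(measurements.transverse_cm, 1),
        "anterior_posterior_cm": round(measurements.anterior_posterior_cm, 1),
        "cranio_caudal_cm": round(measurements.cranio_caudal_cm, 1),
        "prostate_volume_cm3": round(measurements.wp_volume_cm3, 1),
        "peripheral_zone_volume_cm3": round(measurements.pz_volume_cm3, 1),
        "central_gland_volume_cm3": round(measurements.cg_volume_cm3, 1),
        "psa_density_ng_ml2": None if psad is None else round(psad, 3),
        "psa_density_available": psad is not None,
    }

    if lesion_rows:
        parts = [
            f"{r['label']} in the {r['centroid_zone']} at the {r['centroid_region']} "
            f"(slice {r['centroid_slice']}) with probability of CSPCa {r['probability_pct']}%, "
            f"volume {r['volume_cm3']} cm³, minimum ADC "
            f"{r['min_adc_mm2_s']:.2e} mm²/s"
            + (", extending beyond the prostatic capsule" if r["extracapsular"] else "")
            for r in lesion_rows
        ]
        summary = (
            f"{len(lesion_rows)} clinically significant lesion candidate(s) identified: "
            + "; ".join(parts)
            + f". Prostate volume {prostate['prostate_volume_cm3']} cm³"
            + (
                f", PSA density {prostate['psa_density_ng_ml2']} ng/mL²."
                if psad is not None
                else "; PSA density unavailable (no PSA recorded)."
            )
        )
    else:
        summary = (
            "No clinically significant lesion candidates above threshold. "
            f"Prostate volume {prostate['prostate_volume_cm3']} cm³"
            + (
                f", PSA density {prostate['psa_density_ng_ml2']} ng/mL²."
                if psad is not None
                else "; PSA density unavailable (no PSA recorded)."
            )
        )

    patient_block = {
        "name": patient.name,
        "hospital_number": patient.hospital_number,
        "date_of_birth": _fmt_date(patient.date_of_birth),
        "scan_date": _fmt_date(patient.scan_date),
        "age_years": patient.age,
        "psa_ng_ml": patient.psa,
    }
    provenance = {
        "software": "autoprostate",
        "version": _pkg_version,
        "config_hash": config_hash or hashlib.sha256(b"default").hexdigest()[:12],
    }
    return ReportDocument(
        patient=patient_block,
        prostate=prostate,
        lesions=lesion_rows,
        findings_summary=summary,
        provenance=provenance,
    )


def render_json(doc: ReportDocument) -> bytes:
    """Canonical JSON: sorted keys, stable separators, UTF-8 bytes."""
    payload = {
        "patient_details": doc.patient,
        "prostate_size_and_psa_density": doc.prostate,
        "lesion_candidates": doc.lesions,
        "findings_summary": doc.findings_summary,
        "provenance": doc.provenance,
    }
    return json.dumps(payload, sort_keys=True, ensure_ascii=False, separators=(",", ":")).encode(
        "utf-8"
    )


def _row(label: str, value) -> str:
    return f"<tr><th>{_html.escape(label)}</th><td>{_html.escape(str(value))}</td></tr>"


def render_html(doc: ReportDocument, overlays: dict | None = None, out_dir: str | Path | None = None) -> str:
    """Self-contained static HTML with the four report sections in order.

    ``overlays`` maps lesion label -> path of a pre-rendered overlay image
    (written separately, e.g. by the pipeline); missing or mismatched
    overlays are skipped with a comment, never a failure.
    """
    overlays = overlays or {}
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>Prostate MRI Report</title>",
        "<style>body{font-family:sans-serif;max-width:52em;margin:auto}"
        "table{border-collapse:collapse}th,td{border:1px solid #999;"
        "padding:0.3em 0.6em;text-align:left}h2{margin-top:1.4em}</style>",
        "</head><body><h1>Prostate MRI Report</h1>",
    ]

    parts.append(f"<h2>{SECTION_TITLES[0]}</h2><table>")
    p = doc.patient
    for label, key in (
        ("Patient Name", "name"),
        ("Hospital Number", "hospital_number"),
        ("Date of Birth", "date_of_birth"),
        ("Scan Date", "scan_date"),
        ("Age (years)", "age_years"),
        ("PSA (ng/mL)", "psa_ng_ml"),
    ):
        parts.append(_row(label, p[key] if p[key] is not None else "—"))
    parts.append("</table>")

    parts.append(f"<h2>{SECTION_TITLES[1]}</h2><table>")
    pr = doc.prostate
    for label, key in (
        ("Transverse (cm)", "transverse_cm"),
        ("Anterior–Posterior (cm)", "anterior_posterior_cm"),
        ("Cranio–Caudal (cm)", "cranio_caudal_cm"),
        ("Prostate Volume (cm³)", "prostate_volume_cm3"),
        ("Peripheral Zone Volume (cm³)", "peripheral_zone_volume_cm3"),
        ("Central Gland Volume (cm³)", "central_gland_volume_cm3"),
    ):
        parts.append(_row(label, pr[key]))
    psad = pr["psa_density_ng_ml2"]
    parts.append(_row("PSA Density (ng/mL²)", psad if pr["psa_density_available"] else "unavailable"))
    parts.append("</table>")

    parts.append(f"<h2>{SECTION_TITLES[2]}</h2>")
    if doc.lesions:
        parts.append(
            "<table><tr><th>Lesion</th><th>Probability of CSPCa (%)</th>"
            "<th>Volume (cm³)</th><th>Centroid Slice</th><th>Centroid Zone</th>"
            "<th>Centroid Region</th><th>Min ADC (mm²/s)</th><th>Extra-Capsular?</th></tr>"
        )
        for r in doc.lesions:
            parts.append(
                "<tr>"
                + "".join(
                    f"<td>{_html.escape(str(v))}</td>"
                    for v in (
                        r["label"],
                        r["probability_pct"],
                        r["volume_cm3"],
                        r["centroid_slice"],
                        r["centroid_zone"],
                        r["centroid_region"],
                        f"{r['min_adc_mm2_s']:.2e}",
                        str(r["extracapsular"]).lower(),
                    )
                )
                + "</tr>"
            )
        parts.append("</table>")
        for r in doc.lesions:
            img = overlays.get(r["label"])
            if img is not None and Path(img).exists():
                parts.append(
                    f"<p><img src='{_html.escape(str(img))}' "
                    f"alt='{_html.escape(r['label'])} overlay' width='320'></p>"
                )
    else:
        parts.append("<p>No lesion candidates above threshold.</p>")

    parts.append(f"<h2>{SECTION_TITLES[3]}</h2>")
    parts.append(f"<p>{_html.escape(doc.findings_summary)}</p>")
    parts.append(
        f"<hr><small>{_html.escape(doc.provenance['software'])} "
        f"v{_html.escape(doc.provenance['version'])} "
        f"(config {_html.escape(doc.provenance['config_hash'])})</small>"
    )
    parts.append("</body></html>")
    page = "".join(parts)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.html").write_text(page, encoding="utf-8")
    return page
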