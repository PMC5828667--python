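"""82-region cortical/subcortical parcellation labels (AAL-style acronyms).

The parcellation used throughout the pipeline: one representative solution
point per region, one scalar source series per region. Index order is fixed
(1-based region number = list index + 1) so that connectivity matrices are
comparable across subjects and runs.
"""

from __future__ import annotations

# (acronym, full name), left/right interleaved, 82 entries
ROI_TABLE: list[tuple[str, str]] = [
    ("PreCG.L", "Precentral Gyrus Left"),
    ("PreCG.R", "Precentral Gyrus Right"),
    ("SFGdor.L", "Frontal Superior Left"),
    ("SFGdor.R", "Frontal Superior Right"),
    ("ORBsup.L", "Frontal Superior Orbital Left"),
    ("ORBsup.R", "Frontal Superior Orbital Right"),
    ("MFG.L", "Frontal Middle Left"),
    ("MFG.R", "Frontal Middle Right"),
    ("ORBmid.L", "Frontal Middle Orbital Left"),
    ("ORBmid.R", "Frontal Middle Orbital Right"),
    ("IFGoperc.L", "Frontal Inferior Operculum Left"),
    ("IFGoperc.R", "Frontal Inferior Operculum Right"),
    ("IFGtriang.L", "Frontal Inferior Triangularis Left"),
    ("IFGtriang.R", "Frontal Inferior Triangularis Right"),
    ("ORBinf.L", "Frontal Inferior Orbital Left"),
    ("ORBinf.R", "Frontal Inferior Orbital Right"),
    ("ROL.L", "Rolandic Operculum Left"),
    ("ROL.R", "Rolandic Operculum Right"),
    ("SMA.L", "Supplementary Motor Area Left"),
    ("SMA.R", "Supplementary Motor Area Right"),
    ("OLF.L", "Olfactory Left"),
    ("OLF.R", "Olfactory Right"),
    ("SFGmed.L", "Frontal Superior Medial Left"),
    ("SFGmed.R", "Frontal Superior Medial Right"),
    ("ORBsupmed.L", "Frontal Medial Orbital Left"),
    ("ORBsupmed.R", "Frontal Medial Orbital Right"),
    ("REC.L", "Rectus Left"),
    ("REC.R", "Rectus Right"),
    ("INS.L", "Insula Left"),
    ("INS.R", "Insula Right"),
    ("ACG.L", "Cingulum Anterior Left"),
    ("ACG.R", "Cingulum Anterior Right"),
    ("DCG.L", "Cingulum Middle Left"),
    ("DCG.R", "Cingulum Middle Right"),
    ("PCG.L", "Cingulum Posterior Left"),
    ("PCG.R", "Cingulum Posterior Right"),
    ("HIP.L", "Hippocampus Left"),
    ("HIP.R", "Hippocampus Right"),
    ("PHG.L", "ParaHippocampal Left"),
    ("PHG.R", "ParaHippocampal Right"),
    ("AMYG.L", "Amygdala Left"),
    ("AMYG.R", "Amygdala Right"),
    ("CAL.L", "Calcarine Left"),
    ("CAL.R", "Calcarine Right"),
    ("CUN.L", "Cuneus Left"),
    ("CUN.R", "Cuneus Right"),
    ("LING.L", "Lingual Left"),
    ("LING.R", "Lingual Right"),
    ("SOG.L", "Occipital Superior Left"),
    ("SOG.R", "Occipital Superior Right"),
    ("MOG.L", "Occipital Middle Left"),
    ("MOG.R", "Occipital Middle Right"),
    ("IOG.L", "Occipital Inferior Left"),
    ("IOG.R", "Occipital Inferior Right"),
    ("FFG.L", "Fusiform Left"),
    ("FFG.R", "Fusiform Right"),
    ("PoCG.L", "Postcentral Left"),
    ("PoCG.R", "Postcentral Right"),
    ("SPG.L", "Parietal Superior Left"),
    ("SPG.R", "Parietal Superior Right"),
    ("IPL.L", "Parietal Inferior Left"),
    ("IPL.R", "Parietal Inferior Right"),
    ("SMG.L", "SupraMarginal Left"),
    ("SMG.R", "SupraMarginal Right"),
    ("ANG.L", "Angular Left"),
    ("ANG.R", "Angular Right"),
    ("PCUN.L", "Precuneus Left"),
    ("PCUN.R", "Precuneus Right"),
    ("PCL.L", "Paracentral Lobule Left"),
    ("PCL.R", "Paracentral Lobule Right"),
    ("HES.L", "Heschl Left"),
    ("HES.R", "Heschl Right"),
    ("STG.L", "Temporal Superior Left"),
    ("STG.R", "Temporal Superior Right"),
    ("TPOsup.L", "Temporal Pole Superior Left"),
    ("TPOsup.R", "Temporal Pole Superior Right"),
    ("MTG.L", "Temporal Middle Left"),
    ("MTG.R", "Temporal Middle Right"),
    ("TPOmid.L", "Temporal Pole Middle Left"),
    ("TPOmid.R", "Temporal Pole Middle Right"),
    ("ITG.L", "Temporal Inferior Left"),
    ("ITG.R", "Temporal Inferior Right"),
]

ROI_LABELS: list[str] = [acr for acr, _ in ROI_TABLE]

N_ROIS: int = len(ROI_TABLE)

assert N_ROIS == 82


def roi_index(acronym: str) -> int:
    """0-based index of a region acronym; raises KeyError if unknown."""
    try:
        return ROI_LABELS.index(acronym)
    except ValueError:
        raise KeyError(f"unknown ROI acronym: {acronym!r}") from None
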