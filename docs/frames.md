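# Segment frames and marker set

All local frames are right-handed and follow the ISB convention: Y along the
segment long axis pointing proximally/superiorly, X anterior, Z to the
(anatomical) right. Orientation matrices store the axes as columns expressed
in the global frame; each series' origin is the segment's proximal joint
centre.

## Canonical marker set

| Segment   | Markers | Landmark |
|-----------|---------|----------|
| pelvis    | LASI, RASI | left/right anterior superior iliac spine |
|           | LPSI, RPSI | left/right posterior superior iliac spine |
| trunk     | IJ | incisura jugularis (suprasternal notch) |
|           | PX | xiphoid process |
|           | C7 | 7th cervical spinous process |
|           | T8 | 8th thoracic spinous process |
| upper arm | ACR | acromion |
|           | LEL, MEL | lateral/medial humeral epicondyle |
| forearm   | RS, US | radial/ulnar styloid |
| hand      | MC3 | 3rd metacarpal head |
|           | HND2 | dorsal hand |

`PLUGIN_GAIT_ALIASES` in `pitchchain.trial_io` maps plug-in-gait labels
(CLAV, STRN, T10, RSHO, RELB, RWRA, RWRB, RFIN, ...) onto this set per
throwing side.

## Joint centres

- **GH** (glenohumeral) = ACR − 0.07 · body height · ŷ_trunk
- **EJC** (elbow) = midpoint(LEL, MEL)
- **WJC** (wrist) = midpoint(RS, US)

## Constructions

**Pelvis** — origin midpoint(LASI, RASI); Z = unit(RASI − LASI);
X = unit component of (mid-ASIS − mid-PSIS) orthogonal to Z; Y = Z × X.

**Trunk** — origin IJ; Y = unit(mid(IJ, C7) − mid(PX, T8));
X = unit component of (IJ − C7) orthogonal to Y; Z = X × Y.

**Upper arm** — origin GH; Y = unit(GH − EJC);
X = unit(Y × (LEL − MEL)); Z = X × Y.

**Forearm** — origin EJC; Y = unit(EJC − WJC);
X = unit(Y × (RS − US)); Z = X × Y.

**Hand** — origin WJC; Y = unit(WJC − MC3);
X = unit(Y × (HND2 − mid(WJC, MC3))); Z = X × Y.

Degenerate geometry (a cross product or projection with norm below 1e-9) is
reported with the first offending frame index.
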