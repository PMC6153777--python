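# efparse default configuration.
#
# Every knob the extraction pipeline exposes lives here; institutions extend
# the pattern set, heading list, or qualitative map without code changes by
# passing an override YAML that is deep-merged over these defaults.

# Explicit accept list of note-type codes treated as echocardiogram reports.
# Echo codes are institution-specific (commonly ECH-prefixed); candidates are
# surfaced by discover_echo_codes and must be confirmed by a human before
# being listed here. An empty list is a configuration error, never pass-all.
echo_codes: ["ECH01", "ECH02", "ECH03"]

anchors:
  # Phrase used to find candidate echo codes in metadata discovery.
  discovery_phrase: "ejection fraction"
  # Keyword screen for the cascade: a note containing none of these anywhere
  # is logged as no-anchor-keywords. "systolic function" licenses qualitative
  # mentions that never name the ejection fraction outright.
  keywords: ["ejection fraction", "lvef", "ef", "systolic function"]

sampling:
  seed: 0

sections:
  # Curated cardiology headings; a line whose normalized form (lowercase,
  # trimmed, one trailing colon stripped) equals an entry is a section boundary.
  headings:
    - left ventricle
    - right ventricle
    - left atrium
    - right atrium
    - aortic valve
    - mitral valve
    - tricuspid valve
    - pulmonic valve
    - pericardium
    - aorta
    - measurements
    - conclusions
  lv_aliases:
    - left ventricle

patterns:
  # Max number of filler words allowed between an anchor token and the value
  # ("is", "visually estimated at", "around", ...). Bounded so capture never
  # crosses into an unrelated sentence.
  filler_window: 8
  # Plausibility bounds on a captured percentage; candidates outside are
  # skipped and the scan continues (excludes years, heart rates near labels).
  min_value: 1
  max_value: 99
  # Where qualitative matching may look when the LV section has no match:
  # "note" (whole-note fallback) or "lv-section" (LV section only).
  qualitative_scope: note
  # Qualitative phrase inventory: canonical key -> regex alternatives
  # (case-insensitive). Keys must each have an entry in the qualitative map.
  phrasebook:
    hyperdynamic:
      - '(?:left\s+ventricular|lv)\s+systolic\s+function\s+(?:is|appears)\s+hyperdynamic'
      - 'hyperdynamic\s+(?:left\s+ventricular|lv)\s+systolic\s+function'
    normal:
      - '(?:left\s+ventricular|lv)\s+systolic\s+function\s+(?:is|appears)\s+normal'
      - 'normal\s+(?:left\s+ventricular|lv)\s+systolic\s+function'
      - '(?:lvef|left\s+ventricular\s+ejection\s+fraction)\s+(?:is|appears)\s+normal'
    low-normal:
      - '(?:lvef|left\s+ventricular\s+ejection\s+fraction|(?:left\s+ventricular|lv)\s+systolic\s+function)\s+(?:is|appears)?\s*(?:at\s+)?the\s+lower\s+limits?\s+of\s+normal'
      - 'low[-\s]normal\s+(?:left\s+ventricular|lv)\s+systolic\s+function'
    mildly-reduced:
      - '(?:left\s+ventricular|lv)\s+systolic\s+function\s+(?:is|appears)\s+mildly\s+(?:impaired|reduced|decreased|depressed)'
      - 'mildly\s+(?:impaired|reduced|decreased|depressed)\s+(?:left\s+ventricular|lv)\s+systolic\s+function'
    moderately-reduced:
      - '(?:left\s+ventricular|lv)\s+systolic\s+function\s+(?:is|appears)\s+moderately\s+(?:impaired|reduced|decreased|depressed)'
      - 'moderately\s+(?:impaired|reduced|decreased|depressed)\s+(?:left\s+ventricular|lv)\s+systolic\s+function'
    severely-reduced:
      - '(?:left\s+ventricular|lv)\s+systolic\s+function\s+(?:is|appears)\s+severely\s+(?:impaired|reduced|decreased|depressed)'
      - 'severely\s+(?:impaired|reduced|decreased|depressed)\s+(?:left\s+ventricular|lv)\s+systolic\s+function'

normalization:
  # Class-level lookup for qualitative mentions; no numeric EF is imputed.
  # The mildly-reduced -> not-rEF assignment is a documented default choice.
  qualitative_map:
    hyperdynamic: not-rEF
    normal: not-rEF
    low-normal: not-rEF
    mildly-reduced: not-rEF
    moderately-reduced: rEF
    severely-reduced: rEF
  thresholds:
    # Binary rule: EF <= binary_cut -> rEF. Boundary inclusive.
    binary_cut: 40
    # Three-way strata: HFrEF < low, HFmEF in [low, high], HFpEF > high.
    threeway: [40, 50]
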