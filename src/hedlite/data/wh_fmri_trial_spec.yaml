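# Mapping used to unfold the by-trial fMRI event layout into one marker per row.
#
# The trial anchor is the face presentation onset (column `onset`).  The
# stored cross_duration is positive although the cross is displayed *before*
# the anchor, hence sign: before.  response_time is assumed to be measured
# from the face (anchor) onset; the original distribution leaves the
# reference point ambiguous, so it is made explicit here.
anchor_column: onset
derived_events:
  - name: show_cross
    source: cross_duration
    sign: before
  - name: show_face
  - name: show_circle
    source: duration
    role: duration-from-anchor
  - name: key_press
    source: response_time
pass_through:
  - stim_type
  - trigger
  - button_pushed
  - stim_file
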