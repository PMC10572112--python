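# DialectConfig for the PhysioNet `nqmitcsxpd` (neuroQWERTY MIT-CSXPD)
# keystroke archive.
#
# The archive documents per-subject files rather than one pooled table, so
# subject and visit identity come from the file name.  The column mapping
# below is a DEFAULT GUESS: the raw file schema is not documented in the
# analyses this package implements, and anyone downloading the archive must
# validate (and if needed edit) this mapping before use.  Nothing is
# hard-coded — this file is the single place the dialect lives.
key_column: key
press_column: press_time
release_column: release_time
unit: ms
subject_column: null
visit_column: null
filename_pattern: "(?P<subject>[A-Za-z0-9]+)(?:[._-](?P<visit>\\d+))?"
delimiter: ","
has_header: true
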