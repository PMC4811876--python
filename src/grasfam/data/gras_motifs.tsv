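# GRAS motif catalog: name <TAB> region <TAB> pattern
# Pattern language: uppercase residues are literal; `X` and `+` are
# single-position wildcards; `[LIVF]` is a per-position alternative set.
# The DELLA, TVHYNP, LRITG, LXXLL, RVER, XIV, XV and XVI consensi follow the
# published descriptions of the family.  The per-unit consensus strings of the
# five core GRAS-domain motifs (LHRI, VHIID, LHRII, PFYRE, SAW) are synthetic
# placeholder consensi: editable stand-ins with the documented unit
# architecture, not transcriptions of any published alignment image.
DELLA	N_terminal	DELLA
TVHYNP	N_terminal	TVHYNP
XIV	N_terminal	TSVLDTRRSPSPPTSTSTSTL+SS++GGG
XV	N_terminal	++EQS+L+WI+GDV+DPS+G
XVI	N_terminal	RELE+ALLGPDDDD
LHRI	GRAS_domain	LAELLXELNQALL
NLS	GRAS_domain	RKRKXSKKRR
VHIID	GRAS_domain	ARVHIIDFG
LRITG	GRAS_domain	[LIVF]RITG
LHRII	GRAS_domain	LEFLXGNLXXLL
LXXLL	GRAS_domain	LXXLL
PFYRE	GRAS_domain	HPFYREFXESNY
RVER	GRAS_domain	RVER
SAW	GRAS_domain	WQDRXLXAVSAW
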