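# name=nk_ligands
# resolution=2
Bw4	A*23:01
Bw4	A*24:02
Bw4	A*25:01
Bw4	A*32:01
Bw4	B*27:05
Bw4	B*37:01
Bw4	B*38:01
Bw4	B*44:02
Bw4	B*44:03
Bw4	B*47:01
Bw4	B*49:01
Bw4	B*51:01
Bw4	B*52:01
Bw4	B*53:01
Bw4	B*57:01
Bw4	B*58:01
Bw4	B*59:01
Bw6	B*07:02
Bw6	B*08:01
Bw6	B*14:02
Bw6	B*15:01
Bw6	B*18:01
Bw6	B*35:01
Bw6	B*39:01
Bw6	B*40:01
Bw6	B*40:02
Bw6	B*41:01
Bw6	B*42:01
Bw6	B*45:01
Bw6	B*46:01
Bw6	B*48:01
Bw6	B*50:01
Bw6	B*54:01
Bw6	B*55:01
Bw6	B*56:01
C1	C*01:02
C1	C*03:02
C1	C*03:03
C1	C*03:04
C1	C*07:01
C1	C*07:02
C1	C*08:01
C1	C*08:02
C1	C*12:02
C1	C*12:03
C1	C*14:02
C1	C*16:01
C2	C*02:02
C2	C*04:01
C2	C*05:01
C2	C*06:02
C2	C*15:02
C2	C*17:01
C2	C*18:01
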