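>synthetic_FICD_104-445 SYNTHETIC stand-in: seeded average-composition sequence at the length of the human FICD 104-445 construct (not the real sequence)
VSYFELQFDGPVVELKQNLKFYIHRWQRHIFDRWAQFFSEAAEPDILIVVDGRNWFGIDH
DPAWAAEGNSAVRGNPPGKYAVTFLKFKSERTQFFGAEGYLRKMISVIPGDKRLIAEGVP
ISGNYIPANMRPSFNGTDSRLDGFFFKNHKSTPIELLAQPIFQYEWATHLDKGDNSSDNS
VSHAPRLGMFDTHVNGFTKNREEAGGASATTMITKIIRRWKDKSIIVTRRADGSIFLVAN
ALDDDTRFGLAFHLTHVGGLKKAGVSTAPELEERIMSDKAPLDCIGVLEMTLSYTDVFQQ
GRNYPLFSSLAEFQAQPIYGHCRTYAPIGSGWRSLDKNAKGH
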