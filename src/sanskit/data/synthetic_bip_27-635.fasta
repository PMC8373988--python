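>synthetic_BiP_27-635 SYNTHETIC stand-in: seeded average-composition sequence at the length of the hamster BiP 27-635 construct (not the real sequence)
PDDLHKTGVMLEQIQDEGIEEVGEVFWPTAFGTLFTREGTKMSFNVAMTYLGLRDRIGWL
LTWAFEFNAVYWTVVAVGPQEYCVPNTYLDMPQQLAKLLTKWHGRWPYHDSLLACFRGIW
EIGLQPLVIMLYKTDRSARQKKSNPHRRHIASQETLLVIKLSSLALHVISKITDRPPNKI
IEMSNDNCRNGVLAKKPDATSFFNEKQLVRDDASDQEEAMDKPDIMDNSYDPPFSIYMNM
YSLAQYLIELLYQTASVCGFKSGEFEPTRQAPTWIYKVNAENQANKLFVPAGELSPRHAP
EAQIYFSNLNLFGRKRAISPSFQAQQIYEGAQDVVREDVIAGLKANFGLLDDYPMIAIVN
CGLLIHEDDKEFECINYLKEMLNSYFGDFPEIPTYSSVAEYNDIECPFDAFDLEEQRPEQ
TEMGPLHDVGLHSDLELREYYEGIFKSRALESTDLGLLQFNKVIDAKLNLTGYPAERQNG
QASYPARISMTEGRLQTRGERYPMFHGNPAIEDQSLNHLDVELTYQLKSAQNRPKDKLES
MLFRLAKNSPGALEISNSKTKEASGQSDKTHSLMLAIRTTYKPGPDLTFEYWYVLVLYDA
WNGALELLY
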