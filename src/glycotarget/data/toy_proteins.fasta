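>SYN_MEMB1 synthetic Ser/Thr-rich membrane-like protein
WPMSFVQDRTTPRNKYKSSSTSVLVSSGKDFSVRSSLTRFKKKWLGHWGEDNHHLTRLRH
LLPFGTAQVFRITVIGDSVEETFTKHSFTGSWIQTEHIQTSSVAFYSMFKNVDFRLEFSV
NRESGERSAVTNSKVGPTWTDYNTSESVKLDGALTTQAVRVSLETKNCTNLGLKNELVPS
TLSKENCKKRERGMAGYTLVNSPTSNRDGGRVYHLIMVRDHTCLLTASKQNVQTDPLKFW
ITSAYLVPGFKTYFKQGQVFYTEFRLNGHRPLPFYQTVPTTEGMSYGNSLIITGMRGNRG
KAFEDTKLGQTT
>SYN_MEMB2 synthetic Ser/Thr-rich membrane-like protein
DSLGDSKGEMSVTVSGFQEDKYLSTADKMKTFCIDESSKSETRERFIPRLRSMVSGTLNH
TFQKGSSRSRENTIRFVTGSLVGDKTLVITTSRVTVVSLSVDLIMYPLKRKTSRSYRVRT
LKGKLESFILGERVNSEVRFRPFVLGEMSNIVKKWTQVTTVLTSEDFKHDPFFESTLLFF
SAATSWGRERFSRINSYTYLINPPCVQPPRKRSGSPNNSRALLDYRQSENSKTSQSHLAL
VKKNERS
>SYN_MEMB3 synthetic Ser/Thr-rich membrane-like protein
STGKKGGTTKFFVIVSMNYSKADLKNYRRKTLTYMLSYNSGDFNFSTTDKTGVVSDLSEG
GSDRPFDIIMIGLQIKIGYSEKVPPRGSLVHVTLKMRSSFSACSCPSYSKNNQSTTFAET
LNIWAYTSPIKLTNRVKSVTQTIGDPVNHELELATIAIMTAELFELLTFQRSVVTRLVRK
CTFRERDDYTAGTQGNYGKHSRLKRPSSSPVLLGSIYATEWLWKATSKETSSSSIRRIVP
TNFAALEVCIDQTWSGTLGSIHVLTRKSGVWFSREYKLGPFSKIDGLLKQDKATFTLYNR
PISSHCGSGRSSEKMHLLDSGRNTRMVVKQPTTFHNSMIEINVSRTNTHLYDVSKYLFGE
EWDSRAPVRPTLSISATFVSGGMMQLDLQDSSTKKFAPKIGLGTVTPTRGLSMLSNKSFP
GKKSNSAH
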