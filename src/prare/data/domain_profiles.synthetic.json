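[
 {
  "name": "AP",
  "consensus": "PWWMYLRIANFVYCYGFLKWLPIIPKVHKLLWSYNGDYKDPNARPWAHKLHYVAD",
  "threshold": 23.0
 },
 {
  "name": "DNA-pol-III-gamma-tau",
  "consensus": "VYWLCHVANSSCPVEHYLEPNAMRFHPLRSNWVYREGMQCRHSIRPNNHLHKMNRGYAMH",
  "threshold": 24.0
 },
 {
  "name": "DNA-topoisomerase-2",
  "consensus": "PFKHDTQCNTPGKWFGKKMGVWIEEPEDPNTTFHPVRGKTHWRLWPELKCMRRIKRLAKD",
  "threshold": 24.0
 },
 {
  "name": "GAG",
  "consensus": "YASRRFVIWWYFFCFSETSSGDKCEIPICWNDVKEEEIKGKVQATCDHNDHSLMCEWVVPCVTMVVYNDR",
  "threshold": 11.0
 },
 {
  "name": "INT",
  "consensus": "VKNCLWKSRRRPGANYEAYKNLCELLNVWTQQTHPIMEVIPSCLDMSNTWTYPAHEVLCSDTRKAPNESNITQTLKHQFYMITKY",
  "threshold": 10.0
 },
 {
  "name": "Mis12",
  "consensus": "HYYRMCHKMPSYTKTSSMHDTWEGDSKTIPFQVREIRTFQADLRYRVLVK",
  "threshold": 17.0
 },
 {
  "name": "RH",
  "consensus": "TGWPYVRQLWIVGAPNMMTQYLIHILGNARLCNVPCAKRVMQKVKSDWMTDCERCKACTQYPFGP",
  "threshold": 21.0
 },
 {
  "name": "RT",
  "consensus": "VNMETDVLMHTMMHEWRESRAAMCGDIMLEGMRWWMHIDCHHFDLRADQQRFRWQWKQEAREENCEVMQLTCVAYMKYAKLVPIYTQDYKGNPHFVGYPDHGNQGERDPESMLDDDNCRVFCIRCDDWFLILTLGKCSQATILWILLHWCLNYINLDRNT",
  "threshold": -6.0
 },
 {
  "name": "Smc",
  "consensus": "TSCVTMRKKAVFIGHFRDTTSMERESMHYHYIILYEWKPKQKYTWCKINMTANVKCGGSI",
  "threshold": 22.0
 },
 {
  "name": "TRP28",
  "consensus": "LQSCPDQPGWFTRQHIWAYDMNKAHCCHHDTWVQLQCGPTGKWDSFVLFASAWWHRIYEE",
  "threshold": 14.0
 },
 {
  "name": "TolA",
  "consensus": "FYCISDSGMDISYNCNILGINGSHVFAHWYEWVLTSLDAKGFQQKWLLFV",
  "threshold": 26.0
 },
 {
  "name": "mitotic-checkpoint",
  "consensus": "THPTWAGQNHMQCCISHKFTYTGNVNFMQKDWGGIMSYTERFGVHHVRSL",
  "threshold": 25.0
 },
 {
  "name": "recombination-inhibitor",
  "consensus": "CKWICCMVLNTEKYEDHKILQACCSREFAYWWECTFISLNHPHCLCKSQF",
  "threshold": 34.0
 }
]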